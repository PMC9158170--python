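"""One-command orchestration: simulate -> quantify -> stage statistics.

A :class:`RunConfig` bundles every knob (simulation design, stage profiles,
retrieval filter, scoring, statistics) under a single global seed; per-sample
seeds are derived by stable hashing of the sample id, so adding a sample never
perturbs the others and a fixed config yields byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .gene_model import GeneModel
from .quant import FilterParams, ScoringParams, compute_rpkm, quantify_sample
from .simulate import (
    SimulationConfig,
    StageProfile,
    default_bait_panel,
    default_study_profiles,
    derive_sample_seed,
    make_background,
    make_gene,
    simulate_sample,
)
from .stats import StatConfig, compare_stages, detect_outliers
from .quant import junction_ratio, usage_fractions

log = logging.getLogger("spliceprobe")

SITE15_BAITS = ["J14-15A", "J14-15B", "J14-15C"]
SKIP_BAITS = ["J13-15A", "J13-15B", "J13-15C"]
INCLUSION_BAIT = "J13-14"
REFERENCE_BAIT = "J10-11"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "spliceprobe_run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    filter: FilterParams = field(default_factory=FilterParams)
    stat: StatConfig = field(default_factory=StatConfig)
    profiles: list[StageProfile] = field(default_factory=default_study_profiles)
    bait_len: int = 100
    write_reads: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for p in d["profiles"]:
            p["site15_usage"] = dict(p["site15_usage"])
            p["site17_usage"] = dict(p["site17_usage"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig(**d["sim"])
        if "scoring" in d:
            d["scoring"] = ScoringParams(**d["scoring"])
        if "filter" in d:
            d["filter"] = FilterParams(**d["filter"])
        if "stat" in d:
            d["stat"] = StatConfig(**d["stat"])
        if "profiles" in d:
            d["profiles"] = [StageProfile(**p) for p in d["profiles"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Digest of one pipeline run; every number traces to a cell of the run tables."""

    config_hash: str
    seed: int
    version: str
    stages: list[str]
    excluded_samples: list[str]
    mean_rpkm: dict           # bait_id -> {stage -> mean RPKM over kept replicates}
    usage15: dict             # stage -> {A/B/C -> fraction of 14-15 junctions}
    skip_estimate: dict       # stage -> 13-15*/(13-14 + 13-15*) from stage means
    ratio_to_reference: dict  # stage -> {A/B/C -> mean 13-15X / 10-11 RPKM ratio}
    stats_digest: dict        # bait_id -> {H, df, p, dunn_run, n_significant_pairs}
    rpkm: pd.DataFrame = field(repr=False, default=None)
    comparisons: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "excluded_samples": self.excluded_samples,
            "mean_rpkm": self.mean_rpkm,
            "usage15": self.usage15,
            "skip_estimate": self.skip_estimate,
            "ratio_to_reference": self.ratio_to_reference,
            "stats_digest": self.stats_digest,
        }


def _write_tsv(df: pd.DataFrame, path: Path, header_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline TSV, skipping the provenance comment header."""
    return pd.read_csv(path, sep="\t", comment="#")


def quantify_samples(
    baits,
    samples: Sequence[tuple[str, str, str, int, object]],
    scoring: ScoringParams,
    filt: FilterParams,
) -> tuple[pd.DataFrame, dict]:
    """RPKM table over (sample, bait) for pre-simulated or loaded read sets.

    ``samples`` is an iterable of (sample_id, stage, structure, replicate,
    ReadSet).  Returns the tidy table plus per-sample quantification metadata.
    """
    frames = []
    metas = {}
    bait_lens = {b.bait_id: len(b.sequence) for b in baits}
    for sample_id, stage, structure, replicate, reads in samples:
        counts, meta = quantify_sample(baits, reads, scoring, filt)
        df = compute_rpkm(counts, bait_lens, total_reads=len(reads))
        df.insert(0, "sample_id", sample_id)
        df.insert(1, "stage", stage)
        df.insert(2, "structure", structure)
        df.insert(3, "replicate", replicate)
        frames.append(df)
        metas[sample_id] = meta
        log.info("quantified %s: %d reads, %d baits", sample_id, len(reads), len(baits))
    return pd.concat(frames, ignore_index=True), metas


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunSummary:
    """Execute simulate -> quantify -> stats and write all run outputs.

    Writes ``rpkm.tsv``, ``samples.tsv``, ``outliers.tsv``, ``kw.tsv``,
    ``dunn.tsv``, ``summary.json``, ``run_meta.json`` and ``run.log`` under the
    output directory; identical config and seed reproduce the tables byte for
    byte.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    chash = config.config_hash()
    header = f"# spliceprobe {__version__} config_hash={chash} seed={config.seed}"
    try:
        log.info("run start: config_hash=%s seed=%d", chash, config.seed)
        gene = make_gene(config.seed)
        baits = default_bait_panel(gene, bait_len=config.bait_len)
        background = make_background(
            derive_sample_seed(config.seed, "background"),
            config.sim.background_n,
            config.sim.background_len,
            baits=baits,
        )
        reads_dir = out / "reads"
        if config.write_reads:
            reads_dir.mkdir(exist_ok=True)

        samples = []
        sheet_rows = []
        for profile in config.profiles:
            for rep in range(1, config.sim.replicates + 1):
                sample_id = f"{profile.structure}_{profile.stage_label}_r{rep}"
                sseed = derive_sample_seed(config.seed, sample_id)
                reads = simulate_sample(
                    gene, background, profile, config.sim, sseed, sample_id=sample_id
                )
                path = ""
                if config.write_reads:
                    path = str(reads_dir / f"{sample_id}.fastq")
                    reads.to_fastq(path)
                samples.append(
                    (sample_id, profile.stage_label, profile.structure, rep, reads)
                )
                sheet_rows.append(
                    {"sample_id": sample_id, "stage": profile.stage_label,
                     "structure": profile.structure, "replicate": rep,
                     "reads_path": path, "total_reads": len(reads)}
                )
        sheet = pd.DataFrame(sheet_rows)
        _write_tsv(sheet, out / "samples.tsv", header)

        table, metas = quantify_samples(baits, samples, config.scoring, config.filter)
        _write_tsv(table, out / "rpkm.tsv", header)

        excluded, outlier_report = detect_outliers(table, config.stat)
        _write_tsv(outlier_report, out / "outliers.tsv", header)
        kept = table[~table["sample_id"].isin(excluded)]
        log.info("outlier exclusion removed %d sample(s): %s", len(excluded), excluded)

        stage_order = [p.stage_label for p in config.profiles]
        structures = list(dict.fromkeys(p.structure for p in config.profiles))
        kw_rows, dunn_frames = [], []
        comparisons = {}
        for structure in structures:
            sub = kept[kept["structure"] == structure]
            for b in baits:
                cmp_res = compare_stages(
                    sub, b.bait_id, config.stat, stage_order=stage_order
                )
                comparisons[(structure, b.bait_id)] = cmp_res
                kw_rows.append(
                    {"structure": structure, "bait_id": b.bait_id,
                     "H": cmp_res.kw.H, "df": cmp_res.kw.df, "p": cmp_res.kw.p,
                     "tie_correction": cmp_res.kw.tie_correction,
                     "dunn_run": cmp_res.dunn is not None}
                )
                if cmp_res.dunn is not None:
                    d = cmp_res.dunn.table.copy()
                    d.insert(0, "structure", structure)
                    d.insert(1, "bait_id", b.bait_id)
                    dunn_frames.append(d)
        kw_table = pd.DataFrame(kw_rows)
        _write_tsv(kw_table, out / "kw.tsv", header)
        dunn_table = (
            pd.concat(dunn_frames, ignore_index=True)
            if dunn_frames
            else pd.DataFrame(columns=[
                "structure", "bait_id", "group_i", "group_j",
                "mean_rank_diff", "z", "p_raw", "p_adj", "significant",
            ])
        )
        _write_tsv(dunn_table, out / "dunn.tsv", header)

        summary = summarize(
            kept, comparisons, stage_order, chash, config.seed, excluded
        )
        (out / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        meta = {
            "config": config.to_dict(),
            "config_hash": chash,
            "version": __version__,
            "quantification": {
                sid: {
                    "db_size_nt": m["db_size_nt"],
                    "seed_len": m["seed_len"],
                    "truncated": {k: v for k, v in m["truncated"].items() if v},
                }
                for sid, m in metas.items()
            },
        }
        (out / "run_meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        log.info("run complete: %d samples, %d baits", len(samples), len(baits))
        return summary
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def summarize(
    table: pd.DataFrame,
    comparisons: dict,
    stage_order: Sequence[str],
    config_hash: str,
    seed: int,
    excluded: Sequence[str],
) -> RunSummary:
    """Aggregate a (outlier-filtered) RPKM table into the run digest."""
    stages = [s for s in stage_order if s in set(table["stage"])]
    mean_rpkm: dict = {}
    for bait_id, grp in table.groupby("bait_id"):
        by_stage = grp.groupby("stage")["rpkm"].mean()
        mean_rpkm[bait_id] = {s: float(by_stage.get(s, float("nan"))) for s in stages}

    usage15, skip_est, ratios = {}, {}, {}
    for stage in stages:
        site_vals = {
            lab: mean_rpkm.get(b, {}).get(stage, 0.0)
            for lab, b in zip("ABC", SITE15_BAITS)
        }
        frac = usage_fractions(site_vals) if any(site_vals.values()) else None
        usage15[stage] = {k: float(v) for k, v in frac.items()} if frac else None

        skip_sum = sum(mean_rpkm.get(b, {}).get(stage, 0.0) for b in SKIP_BAITS)
        incl = mean_rpkm.get(INCLUSION_BAIT, {}).get(stage, 0.0)
        denom = skip_sum + incl
        skip_est[stage] = float(skip_sum / denom) if denom > 0 else None

        sub = table[table["stage"] == stage]
        wide = sub.pivot_table(index="sample_id", columns="bait_id", values="rpkm")
        stage_ratios = {}
        for lab, b in zip("ABC", SKIP_BAITS):
            if b in wide.columns and REFERENCE_BAIT in wide.columns:
                per_sample = [
                    junction_ratio(num, den)
                    for num, den in zip(wide[b], wide[REFERENCE_BAIT])
                ]
                vals = [r for r in per_sample if r is not None]
                stage_ratios[lab] = float(pd.Series(vals).mean()) if vals else None
        ratios[stage] = stage_ratios

    digest = {}
    for (structure, bait_id), cmp_res in comparisons.items():
        digest[bait_id] = {
            "structure": structure,
            "H": float(cmp_res.kw.H),
            "df": int(cmp_res.kw.df),
            "p": float(cmp_res.kw.p),
            "dunn_run": cmp_res.dunn is not None,
            "n_significant_pairs": (
                int(cmp_res.dunn.table["significant"].sum())
                if cmp_res.dunn is not None else 0
            ),
        }
    return RunSummary(
        config_hash=config_hash,
        seed=seed,
        version=__version__,
        stages=list(stages),
        excluded_samples=list(excluded),
        mean_rpkm=mean_rpkm,
        usage15=usage15,
        skip_estimate=skip_est,
        ratio_to_reference=ratios,
        stats_digest=digest,
        rpkm=table,
        comparisons=comparisons,
    )
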