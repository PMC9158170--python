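"""Human-readable rendering of a pipeline run: plots and a text digest.

Plots are conveniences for inspection; every number they show comes from the
run's tables (``rpkm.tsv`` and the :class:`~spliceprobe.pipeline.RunSummary`).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .pipeline import (
    INCLUSION_BAIT,
    REFERENCE_BAIT,
    SITE15_BAITS,
    SKIP_BAITS,
    RunSummary,
)


def render_summary(summary: RunSummary, out_dir: str | Path) -> list[Path]:
    """Write box plots per bait, the skip-junction ratio plot, site-usage bars
    and a text digest; returns the written paths."""
    if summary.rpkm is None or summary.rpkm.empty:
        raise ValueError("summary holds no RPKM table to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    table = summary.rpkm
    stages = summary.stages

    bait_ids = list(dict.fromkeys(table["bait_id"]))
    ncol = 3
    nrow = -(-len(bait_ids) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel()[len(bait_ids):]:
        ax.set_visible(False)
    for ax, bait_id in zip(axes.ravel(), bait_ids):
        sub = table[table["bait_id"] == bait_id]
        data = [sub.loc[sub["stage"] == s, "rpkm"].to_numpy() for s in stages]
        ax.boxplot(data, tick_labels=stages)
        digest = summary.stats_digest.get(bait_id)
        title = bait_id
        if digest:
            title += f"  (H={digest['H']:.2f}, p={digest['p']:.2g})"
        ax.set_title(title, fontsize=9)
        ax.set_ylabel("RPKM")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    p = out / "rpkm_boxplots.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(8, 4))
    for lab in "ABC":
        series = [
            (summary.ratio_to_reference.get(s) or {}).get(lab) for s in stages
        ]
        ax.plot(stages, [v if v is not None else float("nan") for v in series],
                marker="o", label=f"13-15{lab} / {REFERENCE_BAIT[1:]}")
    ax.set_ylabel("RPKM ratio")
    ax.legend()
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    p = out / "skip_junction_ratios.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(8, 4))
    bottoms = [0.0] * len(stages)
    for lab in "ABC":
        vals = [
            (summary.usage15.get(s) or {}).get(lab, 0.0) or 0.0 for s in stages
        ]
        ax.bar(stages, vals, bottom=bottoms, label=f"site 15{lab}")
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    ax.set_ylabel("fraction of 14-15 junctions")
    ax.legend()
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    p = out / "site15_usage.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    p = out / "digest.txt"
    p.write_text(format_digest(summary))
    written.append(p)
    return written


def format_digest(summary: RunSummary) -> str:
    """Plain-text digest of the run's headline quantities."""
    lines = [
        f"spliceprobe run digest (config {summary.config_hash}, seed {summary.seed})",
        f"stages: {', '.join(summary.stages)}",
        f"excluded samples: {', '.join(summary.excluded_samples) or 'none'}",
        "",
        "per-bait stage comparison (Kruskal-Wallis; Dunn gated at alpha):",
    ]
    for bait_id, d in summary.stats_digest.items():
        lines.append(
            f"  {bait_id:>8s}: H={d['H']:7.2f} df={d['df']} p={d['p']:.3g} "
            f"Dunn={'run, %d significant pairs' % d['n_significant_pairs'] if d['dunn_run'] else 'not run'}"
        )
    lines.append("")
    lines.append("stage  exon14-skip-estimate  site15 usage (A/B/C)")
    for s in summary.stages:
        skip = summary.skip_estimate.get(s)
        usage = summary.usage15.get(s)
        u = (
            "/".join(f"{usage[k]:.2f}" for k in "ABC") if usage else "undefined"
        )
        lines.append(f"  {s:>5s}  {skip if skip is None else format(skip, '.3f'):>8}  {u}")
    return "\n".join(lines) + "\n"
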