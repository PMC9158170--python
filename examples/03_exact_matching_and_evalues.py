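"""Exact-match retrieval and the Karlin-Altschul E-value window.

A hit is the maximal mismatch-free common substring between a read and a bait;
its E-value K*m*n*exp(-lambda*L) says how many such matches arise by chance in
a database of n nucleotides.  The stringency window 4e-60..4e-23 translates
into an exact match-length window, inverted per sample from its database size.
"""

import numpy as np

from spliceprobe import (
    FilterParams,
    ScoringParams,
    evalue_length_window,
    exact_match_hits,
    karlin_altschul_evalue,
)

scoring = ScoringParams()          # lambda=1.28, K=0.46, reward=1 (ungapped blastn-like)
filt = FilterParams()              # E in [4e-60, 4e-23], cap 20,000, a_min 10

for L in (40, 60, 100):
    e = karlin_altschul_evalue(L, m=100, n=10**9, params=scoring)
    status = "inside" if filt.evalue_low <= e <= filt.evalue_high else "outside"
    print(f"match of {L:3d} nt vs 100-nt bait, n=1e9: E = {e:.2e}  ({status} window)")

lo, hi = evalue_length_window(scoring, filt, m=100, n=10**9)
print(f"window inverted to match lengths: L in [{lo}, {hi}]")

rng = np.random.default_rng(0)
bait = "".join("ACGT"[c] for c in rng.integers(0, 4, 100))
read = "T" + bait[20:90] + "ACGTACGTACGTACGTACGTACGTACGTAC"[:30]
(hit,) = [h for h in exact_match_hits(bait, [read]) if h.strand == "+"]
print(f"read vs bait: {hit.match_len}-nt exact match at bait position "
      f"{hit.bait_start}, E = {hit.evalue:.2e}")
# Reads are matched on both strands; a 70-nt identity is far inside the window,
# while typical chance matches (<20 nt) are rejected outright.
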