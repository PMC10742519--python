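"""Pearson significance thresholds and the pathway coordination score.

With few biological replicas, a correlation must be very strong to be
significant: the two-tailed p < 0.05 cutoff is |COR| >= 0.95 for 4 paired
values, and it relaxes as redundant spots add paired values.
"""

from genefabric.coordination import (
    coordination_score,
    cor_pair,
    critical_cor,
    classify_pair,
)

print("Critical |COR| at p < 0.05 (two-tailed):")
for m in (4, 8, 12):
    print(f"  m = {m:2d} paired values -> |COR| >= {critical_cor(m):.2f}")

x = [1.20, 0.85, 1.05, 0.93]   # replicate profile of gene i (normalized units)
y = [0.80, 1.30, 0.98, 1.12]   # gene j moves opposite to gene i
rec = cor_pair(x, y)
print(f"\nAnti-phase pair: COR = {rec.cor:.4f}, p = {rec.p:.4f} -> {classify_pair(rec)}")
print("(ANT: the two genes are significantly antagonistically expressed)")

# pathway-level score from pair-class percentages
syn, ant, ind = 20.76, 20.76, 4.68
print(f"\nCOORD({syn}% SYN, {ant}% ANT, {ind}% IND) = {coordination_score(syn, ant, ind):.2f}")
print("(positive and large: most gene pairs of the pathway are significantly coordinated)")
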