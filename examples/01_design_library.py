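"""How many clones does a shotgun expression library need?

Uses the clone-count calculator: N = ln(1 - P) / ln(1 - insert/genome),
the classic estimate of how many random inserts cover every locus with
probability P.
"""

from dubseq import estimate_clone_requirement

for insert in (1000, 3000, 6000):
    est = estimate_clone_requirement(insert, 4_700_000, 0.99)
    print(
        f"{insert/1000:.0f} kb inserts over a 4.7 Mb genome: "
        f"{est.n_clones} clones for 99% coverage"
    )

# Larger inserts need fewer clones; the numbers are the minimum library
# sizes at which every genomic position is present on some insert with 99%
# probability (real libraries are made several-fold larger for margin).
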