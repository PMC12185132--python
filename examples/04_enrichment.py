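"""Hypergeometric GO overrepresentation of a gene set.

Constructs a background of 60 genes where one term annotates 15 genes,
queries a 12-gene set containing 10 of them, and runs the ORA: p is the
exact hypergeometric upper tail, q the BH-adjusted value across tested
terms.  Also prints the textbook all-hit case whose probability is
1/C(20,5) = 1/15504.
"""

from stressnet import enrich

background = [f"g{i}" for i in range(60)]
go_map = {}
for g in background[:15]:
    go_map.setdefault(g, set()).add("GO:7000001")   # the enriched term
for i, g in enumerate(background):
    go_map.setdefault(g, set()).add(f"GO:700000{2 + i % 3}")  # background noise

query = background[:10] + background[50:52]
results = enrich.ora(query, background, go_map, min_size=10, max_size=500,
                     p_cut=1.0, q_cut=1.0)
print(enrich.results_table(results).to_string(index=False))
print("\ntop term: k hits of K annotated among n drawn from N background;"
      "\nsmall p/q means the query is enriched for that term")

p = enrich.hypergeom_upper(5, 20, 5, 5)
print(f"\nall-hit example P[X >= 5], N=20, K=5, n=5: {p:.6g} "
      f"(= 1/15504 = {1/15504:.6g})")
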