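"""Disorder overlap between HVAL-defined homologs of two proteomes.

Emulates a cold-adapted vs heat-adapted comparison: 30 homolog pairs at
35% identity over 250 aligned columns, where only the cold organism's
side carries a long disordered region, plus unrelated padding proteins.
Reports the relatedness table over the HVAL cutoff grid and the
observed-vs-expected count of disordered related proteins: under
independence one expects related x proteome-disorder-fraction; the
constructed excess mimics disorder concentrated in shared proteins.
"""

from disorderome import build_homolog_map, disorder_overlap
from disorderome.homology import related_over_cutoffs
from disorderome.synthetic import GeneratorConfig, generate_homolog_pairs

pairset = generate_homolog_pairs(
    GeneratorConfig(seed=11),
    n_pairs=30,
    pide_target=35.0,
    aligned_length=250,
    disordered_in="a_only",
    n_unrelated_a=70,
    n_unrelated_b=20,
    org_a="cold",
    org_b="heat",
)

table = related_over_cutoffs(
    pairset.alignments, pairset.tracks_a, pairset.tracks_b,
    cutoffs=(-20, -10, 0, 10, 20, 30), org_a="cold", org_b="heat",
)
print("relatedness by HVAL cutoff (percent of each proteome +/- stderr):")
for _, row in table.iterrows():
    print(
        f"  HVAL>={row['hval_cutoff']:>6.0f}  {row['org']:<5}"
        f"  related {row['pct_related']:5.1f} ± {row['stderr_related']:.1f}"
        f"  related+disordered {row['pct_related_disordered']:5.1f} ± {row['stderr_related_disordered']:.1f}"
    )

homolog_map = build_homolog_map(pairset.alignments, cutoff=10.0, org_a="cold", org_b="heat")
overlap = disorder_overlap(homolog_map, pairset.tracks_a, pairset.tracks_b)
print()
print(f"pairs at HVAL>=10: {overlap.n_pairs}")
print(f"disordered in cold only: {overlap.disordered_in_a_only}")
print(f"disordered in heat only: {overlap.disordered_in_b_only}")
print(f"expected disordered among cold's related proteins (independence): "
      f"{overlap.expected_disordered_a:.1f}; observed: {overlap.observed_disordered_a}")
print()
print("All 30 pairs clear HVAL=10 (35% identity is ~15 points above the curve);")
print("disorder sits only on the cold side, as constructed.")
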