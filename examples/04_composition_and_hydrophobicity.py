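"""Amino-acid composition Z-scores and hydrophobic-class fractions.

Three synthetic proteomes, one with glutamate-biased disordered regions
(a heat-adaptation-like signature), are compared letter-wise: each
frequency is standardised across the panel as a Z-score.  Residues are
also split hydrophobic/not under three published scales (value > 0 =
hydrophobic) to give the coarse two-class view.
"""

from disorderome import aa_frequencies, composition_zscores
from disorderome.composition import annotate_hydrophobicity
from disorderome.synthetic import GeneratorConfig, generate_proteome

panel = []
proteomes = {}
for i, (name, bias) in enumerate(
    [("meso_1", None), ("meso_2", None), ("thermo_E", {"E": 4.0, "K": 1.5})]
):
    config = GeneratorConfig(
        seed=100 + i, n_proteins=120, target_pct_long30=15.0, composition_bias=bias
    )
    sequences, _ = generate_proteome(config, organism_id=name)
    proteomes[name] = sequences
    panel.append(aa_frequencies(sequences, organism_id=name))

composition_zscores(panel)
for profile in panel:
    annotate_hydrophobicity(profile, proteomes[profile.organism_id])

print("glutamate (E) frequency and Z-score per proteome:")
for profile in panel:
    print(f"  {profile.organism_id:<9} freq(E) = {profile.freq['E']:.4f}   z(E) = {profile.z['E']:+.2f}")

print()
print("hydrophobic residue fraction (%) under three scales:")
for profile in panel:
    pct = profile.hydrophobic_pct
    print(
        f"  {profile.organism_id:<9} Kyte-Doolittle {pct['kyte_doolittle']:.1f}"
        f"   Eisenberg {pct['eisenberg']:.1f}   Janin {pct['janin']:.1f}"
    )
print()
print("The E-biased proteome stands out with z(E) > 0 while the neutral")
print("proteomes sit below the panel mean; hydrophobic fractions barely move.")
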