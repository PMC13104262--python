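"""Benchmark curation: canonical-residue proteins and Lipinski-style ligands.

Complexes are kept only if the protein uses the 20 canonical amino acids and
the ligand satisfies MW <= 500 Da, logP <= 5, HBD <= 5, HBA <= 10 (all
inclusive).  The filter consumes plain descriptor records; with RDKit
installed, descriptors can be computed directly from SMILES.
"""

from dockselect.curation import (
    LigandDescriptors,
    ProteinResidueRecord,
    curate,
    descriptors_from_smiles,
)

proteins = [
    ProteinResidueRecord("1AAA", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
    ProteinResidueRecord("2BBB", "MKTUYIAKQR"),          # selenocysteine -> fails
    ProteinResidueRecord("3CCC", "ACDEFGHIKLMNPQRSTVWY"),
    ProteinResidueRecord("4DDD", "MKTAYIAK"),
]
ligands = [
    descriptors_from_smiles("1AAA", "CC(=O)Oc1ccccc1C(=O)O"),          # aspirin
    LigandDescriptors("2BBB", mol_weight=320.0, logp=1.2, hbd=2, hba=5),
    LigandDescriptors("3CCC", mol_weight=612.0, logp=3.0, hbd=2, hba=8),  # too heavy
    LigandDescriptors("4DDD", mol_weight=410.0, logp=4.9, hbd=5, hba=10),  # boundary, passes
]

report = curate(proteins, ligands)
print("retained:", sorted(report.retained))
for iid, reason in sorted(report.rejections.items()):
    print(f"rejected {iid}: {reason}")
print(f"{report.n_retained} kept + {report.n_rejected} rejected "
      f"= {report.n_retained + report.n_rejected} input complexes")
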