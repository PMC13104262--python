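"""Two-stage benchmark curation: canonical-residue proteins, Lipinski-style ligands.

The filter consumes plain descriptor records so it is testable without a
chemistry toolkit; an optional adapter computes the descriptors with RDKit
(molecular weight, Crippen logP, Lipinski donor/acceptor counts) when that
package is available.  All four ligand thresholds are inclusive:
MW <= 500 Da, logP <= 5, HBD <= 5, HBA <= 10.  Proteins pass only if every
residue is one of the 20 canonical one-letter codes; ambiguity codes (B, Z,
X) and noncanonical residues (U, O) fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CANONICAL_RESIDUES",
    "LigandDescriptors",
    "ProteinResidueRecord",
    "CurationReport",
    "ligand_passes",
    "protein_passes",
    "curate",
    "descriptors_from_smiles",
    "read_descriptor_csv",
    "read_residue_fasta",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

MAX_MOL_WEIGHT = 500.0  # Da
MAX_LOGP = 5.0
MAX_HBD = 5
MAX_HBA = 10


@dataclass(frozen=True)
class LigandDescriptors:
    instance_id: str
    mol_weight: float
    logp: float
    hbd: int
    hba: int

    def __post_init__(self) -> None:
        for name in ("mol_weight", "logp", "hbd", "hba"):
            if getattr(self, name) is None:
                raise ValueError(f"missing descriptor {name} for {self.instance_id}")
        if not self.mol_weight > 0:
            raise ValueError(f"mol_weight must be > 0 for {self.instance_id}")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError(f"hbd/hba must be >= 0 for {self.instance_id}")


@dataclass(frozen=True)
class ProteinResidueRecord:
    instance_id: str
    residue_codes: str

    def __post_init__(self) -> None:
        if not self.residue_codes:
            raise ValueError(f"empty residue record for {self.instance_id}")


def ligand_passes(d: LigandDescriptors) -> bool:
    """True iff all four Lipinski-style thresholds hold (inclusive)."""
    return (
        d.mol_weight <= MAX_MOL_WEIGHT
        and d.logp <= MAX_LOGP
        and d.hbd <= MAX_HBD
        and d.hba <= MAX_HBA
    )


def _first_ligand_failure(d: LigandDescriptors) -> str | None:
    if d.mol_weight > MAX_MOL_WEIGHT:
        return "mol_weight"
    if d.logp > MAX_LOGP:
        return "logp"
    if d.hbd > MAX_HBD:
        return "hbd"
    if d.hba > MAX_HBA:
        return "hba"
    return None


def protein_passes(p: ProteinResidueRecord) -> bool:
    """True iff every residue code is canonical."""
    return set(p.residue_codes.upper()) <= CANONICAL_RESIDUES


@dataclass
class CurationReport:
    retained: set[str] = field(default_factory=set)
    rejections: dict[str, str] = field(default_factory=dict)  # id -> first failed criterion

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def curate(
    proteins: list[ProteinResidueRecord],
    ligands: list[LigandDescriptors],
) -> CurationReport:
    """Retain complexes passing both filters; report first failed criterion otherwise.

    The protein check is applied first, so a complex failing both filters is
    reported once with reason ``noncanonical_residue``.
    """
    prot_by_id = {p.instance_id: p for p in proteins}
    lig_by_id = {d.instance_id: d for d in ligands}
    if set(prot_by_id) != set(lig_by_id):
        only_p = sorted(set(prot_by_id) - set(lig_by_id))
        only_l = sorted(set(lig_by_id) - set(prot_by_id))
        raise ValueError(
            f"mismatched record keys; protein-only={only_p[:5]}, ligand-only={only_l[:5]}"
        )
    report = CurationReport()
    for iid in prot_by_id:
        if not protein_passes(prot_by_id[iid]):
            report.rejections[iid] = "noncanonical_residue"
            continue
        reason = _first_ligand_failure(lig_by_id[iid])
        if reason is not None:
            report.rejections[iid] = reason
            continue
        report.retained.add(iid)
    return report


def descriptors_from_smiles(instance_id: str, smiles: str) -> LigandDescriptors:
    """RDKit adapter: MW, Crippen logP, and Lipinski donor/acceptor counts.

    Requires the optional ``rdkit`` dependency; the logP dialect is Crippen's
    atom-contribution estimate.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {instance_id}: {smiles!r}")
    return LigandDescriptors(
        instance_id=instance_id,
        mol_weight=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
    )


def read_descriptor_csv(path) -> list[LigandDescriptors]:
    """Read ``instance_id,mol_weight,logp,hbd,hba`` records."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"instance_id": str})
    return [
        LigandDescriptors(
            instance_id=r.instance_id,
            mol_weight=float(r.mol_weight),
            logp=float(r.logp),
            hbd=int(r.hbd),
            hba=int(r.hba),
        )
        for r in df.itertuples(index=False)
    ]


def read_residue_fasta(path) -> list[ProteinResidueRecord]:
    """Read residue records from FASTA (sequence = one-letter residue codes)."""
    from Bio import SeqIO

    return [
        ProteinResidueRecord(instance_id=rec.id, residue_codes=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
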