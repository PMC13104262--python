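"""Instances, portfolios, performance tables, manifests and fold splits.

On-disk formats
---------------
* Pose-evaluation table: CSV with header
  ``instance_id,solver_id,postprocess,rmsd,pb_valid`` (pb_valid as 0/1, UTF-8,
  '.' decimal separator).
* Embedding store: HDF5 with one group per complex, datasets
  ``/<instance_id>/protein`` (float32, n_residues x d_P) and
  ``/<instance_id>/ligand`` (float32, d_L).
* Benchmark manifest: YAML with keys ``name, tables, embeddings, blocklist,
  regime``.

The solver order inside a :class:`Portfolio` is the tie-break priority
everywhere downstream: any argmax tie resolves to the earliest solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .scoring import PoseEvaluation, PostProcess, ScoringConfig, composite_score, success_label

__all__ = [
    "Instance",
    "SolverConfig",
    "Portfolio",
    "PerformanceTable",
    "BenchmarkManifest",
    "FoldSplit",
    "load_performance_table",
    "build_mixed_portfolio",
    "apply_blocklist",
    "make_kfold",
    "save_embeddings",
    "load_embeddings",
]

POSE_CSV_COLUMNS = ["instance_id", "solver_id", "postprocess", "rmsd", "pb_valid"]


@dataclass
class Instance:
    """One protein-ligand complex with its precomputed embeddings.

    ``protein_embedding`` is a per-residue matrix (n_residues x d_P) from a
    protein language model; ``ligand_embedding`` is a single pooled vector
    (d_L) from a chemical language model.
    """

    instance_id: str
    protein_embedding: np.ndarray
    ligand_embedding: np.ndarray
    benchmark_tag: str = ""

    def __post_init__(self) -> None:
        self.protein_embedding = np.asarray(self.protein_embedding, dtype=np.float32)
        self.ligand_embedding = np.asarray(self.ligand_embedding, dtype=np.float32)
        if self.protein_embedding.ndim != 2 or self.protein_embedding.shape[0] < 1:
            raise ValueError("protein_embedding must be (n_residues >= 1, d_P)")
        if self.ligand_embedding.ndim != 1:
            raise ValueError("ligand_embedding must be a vector")
        if not (
            np.all(np.isfinite(self.protein_embedding))
            and np.all(np.isfinite(self.ligand_embedding))
        ):
            raise ValueError(f"non-finite embedding values for {self.instance_id}")


@dataclass(frozen=True)
class SolverConfig:
    """One portfolio member: a base docking pipeline plus a post-processing tag."""

    solver_id: str
    base_name: str
    postprocess: PostProcess = PostProcess.NONE


@dataclass
class Portfolio:
    """Ordered solver set; the order defines argmax tie-break priority."""

    solvers: list[SolverConfig]

    def __post_init__(self) -> None:
        if len(self.solvers) < 2:
            raise ValueError("a portfolio needs at least 2 solvers")
        ids = [s.solver_id for s in self.solvers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate solver_ids in portfolio")
        pairs = [(s.base_name, s.postprocess) for s in self.solvers]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (base_name, postprocess) pairs in portfolio")

    @property
    def m(self) -> int:
        return len(self.solvers)

    @property
    def solver_ids(self) -> list[str]:
        return [s.solver_id for s in self.solvers]

    def index_of(self, solver_id: str) -> int:
        try:
            return self.solver_ids.index(solver_id)
        except ValueError:
            raise KeyError(f"solver {solver_id!r} not in portfolio") from None


@dataclass
class PerformanceTable:
    """Dense instances x solvers matrices of raw and derived pose outcomes.

    ``scores`` holds composite scores in [0, 1]; ``success_strict`` /
    ``success_relaxed`` the binary criteria; ``missing_mask`` flags cells for
    which no pose evaluation existed (scored 0 / failure by convention, since
    a solver that produces no pose cannot succeed).
    """

    instance_ids: list[str]
    portfolio: Portfolio
    rmsd: np.ndarray
    pb_valid: np.ndarray
    scores: np.ndarray
    success_strict: np.ndarray
    success_relaxed: np.ndarray
    missing_mask: np.ndarray
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        shape = (len(self.instance_ids), self.portfolio.m)
        for name in ("rmsd", "pb_valid", "scores", "success_strict", "success_relaxed", "missing_mask"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")
        if np.any(self.success_strict > self.success_relaxed):
            raise ValueError("strict success cannot exceed relaxed success")

    @property
    def n(self) -> int:
        return len(self.instance_ids)

    @property
    def m(self) -> int:
        return self.portfolio.m

    def metric_matrix(self, metric: str) -> np.ndarray:
        """Return the (n, m) matrix for 'strict', 'relaxed' or 'mean_score'."""
        if metric == "strict":
            return self.success_strict.astype(float)
        if metric == "relaxed":
            return self.success_relaxed.astype(float)
        if metric == "mean_score":
            return self.scores
        raise ValueError(f"unknown metric {metric!r}")

    def subset(self, indices) -> "PerformanceTable":
        """Row-subset the table (e.g. one fold), preserving the portfolio."""
        idx = np.asarray(indices)
        return PerformanceTable(
            instance_ids=[self.instance_ids[i] for i in idx],
            portfolio=self.portfolio,
            rmsd=self.rmsd[idx],
            pb_valid=self.pb_valid[idx],
            scores=self.scores[idx],
            success_strict=self.success_strict[idx],
            success_relaxed=self.success_relaxed[idx],
            missing_mask=self.missing_mask[idx],
            scoring=self.scoring,
        )

    def to_csv(self, path) -> None:
        """Write the observed (non-missing) cells in the pose-evaluation CSV schema."""
        rows = []
        for i, iid in enumerate(self.instance_ids):
            for j, solver in enumerate(self.portfolio.solvers):
                if self.missing_mask[i, j]:
                    continue
                rows.append(
                    {
                        "instance_id": iid,
                        "solver_id": solver.solver_id,
                        "postprocess": solver.postprocess.value,
                        "rmsd": self.rmsd[i, j],
                        "pb_valid": int(self.pb_valid[i, j]),
                    }
                )
        # %.17g guarantees float64 round-trips bit-exactly through the text form
        pd.DataFrame(rows, columns=POSE_CSV_COLUMNS).to_csv(
            path, index=False, float_format="%.17g")


def load_performance_table(
    csv_path,
    portfolio: Portfolio,
    scoring: ScoringConfig = ScoringConfig(),
) -> PerformanceTable:
    """Build a dense :class:`PerformanceTable` from a pose-evaluation CSV.

    Each (instance, solver) pair may appear at most once; rows naming solvers
    absent from the portfolio are an error.  Absent cells are scored 0 with
    the missing-mask set.
    """
    df = pd.read_csv(csv_path, dtype={"instance_id": str, "solver_id": str},
                     float_precision="round_trip")
    missing_cols = set(POSE_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"pose CSV missing columns: {sorted(missing_cols)}")
    unknown = set(df["solver_id"]) - set(portfolio.solver_ids)
    if unknown:
        raise ValueError(f"unknown solver_id(s) not in portfolio: {sorted(unknown)}")
    dup = df.duplicated(subset=["instance_id", "solver_id"])
    if dup.any():
        bad = df.loc[dup, ["instance_id", "solver_id"]].iloc[0]
        raise ValueError(
            f"duplicate (instance, solver) row: ({bad.instance_id}, {bad.solver_id})"
        )

    instance_ids = list(dict.fromkeys(df["instance_id"]))  # first-seen order
    n, m = len(instance_ids), portfolio.m
    row_of = {iid: i for i, iid in enumerate(instance_ids)}

    rmsd = np.zeros((n, m))
    pb = np.zeros((n, m), dtype=int)
    scores = np.zeros((n, m))
    s_strict = np.zeros((n, m), dtype=int)
    s_relaxed = np.zeros((n, m), dtype=int)
    missing = np.ones((n, m), dtype=bool)

    for rec in df.itertuples(index=False):
        i = row_of[rec.instance_id]
        j = portfolio.index_of(rec.solver_id)
        ev = PoseEvaluation(
            instance_id=rec.instance_id,
            solver_id=rec.solver_id,
            rmsd=float(rec.rmsd),
            pb_valid=bool(int(rec.pb_valid)),
            postprocess=PostProcess(rec.postprocess),
        )
        rmsd[i, j] = ev.rmsd
        pb[i, j] = int(ev.pb_valid)
        scores[i, j] = composite_score(ev, scoring)
        s_strict[i, j] = success_label(ev, "strict", scoring)
        s_relaxed[i, j] = success_label(ev, "relaxed", scoring)
        missing[i, j] = False

    return PerformanceTable(
        instance_ids=instance_ids,
        portfolio=portfolio,
        rmsd=rmsd,
        pb_valid=pb,
        scores=scores,
        success_strict=s_strict,
        success_relaxed=s_relaxed,
        missing_mask=missing,
        scoring=scoring,
    )


def build_mixed_portfolio(base_solvers: list[SolverConfig], variants) -> Portfolio:
    """Cross base pipelines with post-processing variants into one portfolio.

    Preserves base order (outer) then variant order (inner); e.g. 24 base
    pipelines x {none, relaxation} gives a 48-solver mixed portfolio in which
    a relaxed pipeline is a distinct solver.
    """
    if not base_solvers:
        raise ValueError("base solver list is empty")
    variants = [PostProcess(v) for v in variants]
    if not variants:
        raise ValueError("variant set is empty")
    solvers = []
    for base in base_solvers:
        for v in variants:
            suffix = "" if v == PostProcess.NONE else f" ({v.value})"
            solvers.append(
                SolverConfig(
                    solver_id=f"{base.base_name}{suffix}",
                    base_name=base.base_name,
                    postprocess=v,
                )
            )
    return Portfolio(solvers=solvers)


def apply_blocklist(table: PerformanceTable, blocklist) -> PerformanceTable:
    """Drop blocklisted instances (e.g. training-corpus overlaps) from a table."""
    blocklist = set(blocklist)
    keep = [i for i, iid in enumerate(table.instance_ids) if iid not in blocklist]
    removed = table.n - len(keep)
    if removed:
        warnings.warn(f"blocklist removed {removed} of {table.n} instances", stacklevel=2)
    if not keep:
        warnings.warn("blocklist removed every instance; table is empty", stacklevel=2)
    out = table.subset(keep) if keep else _empty_like(table)
    return out


def _empty_like(table: PerformanceTable) -> PerformanceTable:
    shape = (0, table.m)
    return PerformanceTable(
        instance_ids=[],
        portfolio=table.portfolio,
        rmsd=np.zeros(shape),
        pb_valid=np.zeros(shape, dtype=int),
        scores=np.zeros(shape),
        success_strict=np.zeros(shape, dtype=int),
        success_relaxed=np.zeros(shape, dtype=int),
        missing_mask=np.zeros(shape, dtype=bool),
        scoring=table.scoring,
    )


@dataclass
class FoldSplit:
    """Deterministic k-fold partition; each fold serves once as the test set."""

    fold_assignments: dict[str, int]
    k: int
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return [iid for iid, f in self.fold_assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [iid for iid, f in self.fold_assignments.items() if f != fold]


def make_kfold(instance_ids: list[str], k: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded shuffle then round-robin fold assignment (sizes differ by <= 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(instance_ids)
    if n < k:
        raise ValueError(f"need at least k={k} instances, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = {instance_ids[idx]: pos % k for pos, idx in enumerate(order)}
    return FoldSplit(fold_assignments=assignments, k=k, seed=seed)


def save_embeddings(instances: list[Instance], path) -> None:
    """Write instances to the hierarchical embedding store (float32)."""
    with h5py.File(path, "w") as f:
        for inst in instances:
            grp = f.create_group(inst.instance_id)
            grp.create_dataset("protein", data=inst.protein_embedding.astype(np.float32))
            grp.create_dataset("ligand", data=inst.ligand_embedding.astype(np.float32))
            grp.attrs["benchmark_tag"] = inst.benchmark_tag


def load_embeddings(path, instance_ids=None) -> dict[str, Instance]:
    """Load (a subset of) the embedding store into Instance objects."""
    out: dict[str, Instance] = {}
    with h5py.File(path, "r") as f:
        keys = list(f.keys()) if instance_ids is None else list(instance_ids)
        for iid in keys:
            if iid not in f:
                raise KeyError(f"instance {iid!r} not in embedding store")
            grp = f[iid]
            out[iid] = Instance(
                instance_id=iid,
                protein_embedding=grp["protein"][()],
                ligand_embedding=grp["ligand"][()],
                benchmark_tag=grp.attrs.get("benchmark_tag", ""),
            )
    return out


@dataclass
class BenchmarkManifest:
    """Pointer file tying a performance table, embeddings and a blocklist together."""

    name: str
    performance_table_path: str
    embedding_store_path: str
    blocklist: set[str] = field(default_factory=set)
    regime: str = "separated"

    def __post_init__(self) -> None:
        if self.regime not in ("mixed", "separated"):
            raise ValueError(f"regime must be 'mixed' or 'separated', got {self.regime!r}")

    @classmethod
    def load(cls, path) -> "BenchmarkManifest":
        path = Path(path)
        with open(path) as f:
            raw = yaml.safe_load(f)
        base = path.parent
        table = base / raw["tables"]
        emb = base / raw["embeddings"]
        blocklist: set[str] = set()
        if raw.get("blocklist"):
            bl_path = base / raw["blocklist"]
            if bl_path.exists():
                blocklist = {
                    line.strip() for line in bl_path.read_text().splitlines() if line.strip()
                }
        for p in (table, emb):
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing path: {p}")
        return cls(
            name=raw["name"],
            performance_table_path=str(table),
            embedding_store_path=str(emb),
            blocklist=blocklist,
            regime=raw.get("regime", "separated"),
        )
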