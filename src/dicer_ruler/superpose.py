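"""Least-squares rigid-body superposition of Cα coordinate sets.

The optimal rotation is the classic SVD (Kabsch) solution with the
determinant correction that excludes reflections, computed through
``scipy.spatial.transform.Rotation.align_vectors``. Domain-level RMSDs are
evaluated under the *global* transform, without refitting, so that the
per-domain values decompose the global fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import CoordinateSet, Structure, select_atoms

__all__ = [
    "SuperpositionResult",
    "DomainSpan",
    "SuperpositionError",
    "pair_common_calpha",
    "kabsch",
    "rmsd_subset",
    "superpose_structures",
    "read_domains",
]


class SuperpositionError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper orthonormal (det = +1)
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å, minimized over rigid transforms
    n_atoms: int
    per_domain_rmsd: Optional[dict[str, float]] = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map target-frame coordinates into the reference frame."""
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def save_matrix(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"matrix": self.to_matrix4().tolist(), "rmsd": self.rmsd,
             "n_atoms": self.n_atoms}, indent=2) + "\n")


@dataclass
class DomainSpan:
    """Named residue range(s), e.g. the helicase / PAZ / RNase III regions."""

    name: str
    ranges: list[tuple[str, int, int]]  # (chain_id, start, end) inclusive

    def __post_init__(self) -> None:
        for chain, start, end in self.ranges:
            if start > end:
                raise ValueError(
                    f"domain {self.name!r}: start {start} > end {end}")

    def contains(self, label: tuple[str, int, str]) -> bool:
        chain, number, _atom = label
        return any(c == chain and s <= number <= e
                   for c, s, e in self.ranges)


def pair_common_calpha(
    ref: Structure,
    tgt: Structure,
    correspondence: Optional[dict[tuple[str, int], tuple[str, int]]] = None,
    atom_name: str = "CA",
) -> tuple[CoordinateSet, CoordinateSet]:
    """Build equally sized, order-matched Cα coordinate sets.

    ``correspondence`` maps reference ``(chain, number)`` to target
    ``(chain, number)``; by default residues are matched on identical
    (chain, number). Residues missing the selected atom in either structure
    are dropped symmetrically. At least 3 pairs are required.
    """
    tgt_index = tgt.residue_index()
    ref_labels, ref_xyz, tgt_labels, tgt_xyz = [], [], [], []
    for res in ref.residues:
        key = (res.chain_id, res.number)
        tkey = correspondence.get(key) if correspondence is not None else key
        if tkey is None:
            continue
        tres = tgt_index.get((tkey[0], tkey[1], ""))
        if tres is None:
            continue
        a_ref, a_tgt = res.atom(atom_name), tres.atom(atom_name)
        if a_ref is None or a_tgt is None:
            continue
        ref_labels.append((res.chain_id, res.number, atom_name))
        ref_xyz.append(a_ref.position)
        tgt_labels.append((tres.chain_id, tres.number, atom_name))
        tgt_xyz.append(a_tgt.position)
    if len(ref_labels) < 3:
        raise SuperpositionError(
            f"only {len(ref_labels)} corresponding {atom_name} pairs between "
            f"{ref.id!r} and {tgt.id!r}; need at least 3")
    return (CoordinateSet(ref_labels, np.vstack(ref_xyz)),
            CoordinateSet(tgt_labels, np.vstack(tgt_xyz)))


def kabsch(P: CoordinateSet, Q: CoordinateSet) -> SuperpositionResult:
    """Optimal rigid transform of Q onto P and the minimized RMSD.

    Returns rotation R and translation t such that ``R q + t`` best matches
    P in the least-squares sense; R is a proper rotation (det = +1) even for
    chirality-breaking inputs.
    """
    if len(P) != len(Q):
        raise SuperpositionError(
            f"coordinate sets differ in size ({len(P)} vs {len(Q)})")
    n = len(P)
    if n < 3:
        raise SuperpositionError(f"need at least 3 atoms, got {n}")
    p, q = P.coords, Q.coords
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(p - pc, q - qc)
    R = rot.as_matrix()
    t = pc - R @ qc
    moved = q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=n)


def rmsd_subset(P: CoordinateSet, Q: CoordinateSet,
                transform: SuperpositionResult,
                subset: Union[DomainSpan, Sequence[int]]) -> float:
    """RMSD of a subset of paired atoms under the *global* transform.

    No refit is performed, so per-domain values decompose the global fit.
    ``subset`` is a :class:`DomainSpan` (matched against P's labels) or an
    index sequence.
    """
    if len(P) != len(Q):
        raise SuperpositionError("coordinate sets differ in size")
    if isinstance(subset, DomainSpan):
        idx = [i for i, lab in enumerate(P.labels) if subset.contains(lab)]
    else:
        idx = list(subset)
    if not idx:
        raise SuperpositionError("subset selects no paired atoms")
    moved = transform.apply(Q.coords[idx])
    return float(np.sqrt(np.mean(np.sum((moved - P.coords[idx]) ** 2,
                                        axis=1))))


def superpose_structures(
    ref: Structure,
    tgt: Structure,
    domains: Optional[Sequence[DomainSpan]] = None,
    correspondence: Optional[dict] = None,
    atom_name: str = "CA",
) -> SuperpositionResult:
    """Pair common Cα atoms, fit globally, and (optionally) decompose the
    fit into per-domain RMSDs."""
    P, Q = pair_common_calpha(ref, tgt, correspondence=correspondence,
                              atom_name=atom_name)
    result = kabsch(P, Q)
    if domains:
        result.per_domain_rmsd = {}
        for span in domains:
            try:
                result.per_domain_rmsd[span.name] = rmsd_subset(
                    P, Q, result, span)
            except SuperpositionError:
                result.per_domain_rmsd[span.name] = float("nan")
    return result


def read_domains(path: str | Path) -> list[DomainSpan]:
    """Read domain spans from a TSV with columns name, chain_id, start, end.

    Several rows may share a name (multi-range domains)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["name", "chain_id", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    spans: dict[str, DomainSpan] = {}
    for _, row in df.iterrows():
        rng = (row["chain_id"], int(row["start"]), int(row["end"]))
        if row["name"] in spans:
            spans[row["name"]].ranges.append(rng)
        else:
            spans[row["name"]] = DomainSpan(row["name"], [rng])
    return list(spans.values())
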