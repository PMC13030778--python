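"""Functional-site tables and residue correspondence between orthologs.

A :class:`ResidueMap` is the machine form of a functional-site table for one
structure: for each named site (the two RNase III catalytic centers and the
PAZ 3'/5' terminal-nucleotide pockets) a list of (chain, author number,
expected amino acid) entries. Entries whose residue could not be assigned in
an ortholog alignment are stored as unresolved ("?") and skipped by all
geometry downstream.

Correspondence between a reference enzyme and an ortholog is established by
deterministic pairwise global alignment with affine gaps (BLOSUM62 by
default), and site annotations are transferred along the alignment.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .structure_io import Structure

__all__ = [
    "SITE_NAMES",
    "SiteEntry",
    "SiteDefinition",
    "ResidueMap",
    "AlignmentResult",
    "AlignmentError",
    "SiteFileError",
    "Discrepancy",
    "align_global",
    "transfer_sites",
    "read_sites",
    "write_sites",
    "read_all_sites",
    "validate_map",
    "read_fasta",
    "table1_sites_path",
    "simple_matrix",
    "default_matrix",
]

SITE_NAMES = ("RIII_A", "RIII_B", "pocket_3prime", "pocket_5prime")
#: Sites the ruler measurement needs, paired pocket <-> catalytic center.
RULER_PAIRS = (("pocket_3prime", "RIII_A"), ("pocket_5prime", "RIII_B"))

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
UNRESOLVED = "?"


class AlignmentError(ValueError):
    pass


class SiteFileError(ValueError):
    pass


@dataclass(frozen=True)
class SiteEntry:
    chain_id: str
    number: Optional[int]  # author residue number; None when unresolved
    expected_aa: str  # one-letter code, or "?" when unresolved

    @property
    def resolved(self) -> bool:
        return self.number is not None


@dataclass
class SiteDefinition:
    site_name: str
    entries: list[SiteEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"site {self.site_name!r} has no entries")

    @property
    def resolved_entries(self) -> list[SiteEntry]:
        return [e for e in self.entries if e.resolved]

    @property
    def unresolved_count(self) -> int:
        return sum(1 for e in self.entries if not e.resolved)


@dataclass
class ResidueMap:
    structure_id: str
    sites: list[SiteDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.site_name for s in self.sites]
        if len(names) != len(set(names)):
            raise ValueError("duplicate site names in residue map")

    def site(self, name: str) -> SiteDefinition:
        for s in self.sites:
            if s.site_name == name:
                return s
        raise KeyError(f"map for {self.structure_id!r} has no site {name!r}")

    def has_site(self, name: str) -> bool:
        return any(s.site_name == name for s in self.sites)

    @property
    def ruler_ready(self) -> bool:
        """True when all four ruler sites carry at least one resolved entry."""
        return all(
            self.has_site(n) and len(self.site(n).resolved_entries) >= 1
            for n in SITE_NAMES
        )


@dataclass
class AlignmentResult:
    """Global alignment of two amino-acid sequences.

    ``ref_to_tgt`` maps 1-based reference residue indices to 1-based target
    indices, or None for positions aligned opposite a gap.
    """

    aligned_ref: str
    aligned_tgt: str
    score: float
    ref_to_tgt: dict[int, Optional[int]]

    @property
    def ref_seq(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def tgt_seq(self) -> str:
        return self.aligned_tgt.replace("-", "")


def simple_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    """Uniform match/mismatch substitution table over the 20 aa letters + X."""
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = match if (a == b and a != "X") else mismatch
    return m


@functools.lru_cache(maxsize=1)
def default_matrix() -> substitution_matrices.Array:
    """BLOSUM62 with X scoring -1 (a plain mismatch) against everything."""
    m = substitution_matrices.load("BLOSUM62")
    for a in m.alphabet:
        m["X", a] = -1.0
        m[a, "X"] = -1.0
    return m


def _check_sequence(seq: str, which: str) -> None:
    if not seq:
        raise AlignmentError(f"{which} sequence is empty")
    bad = set(seq) - AA_ALPHABET - {"X"}
    if bad:
        raise AlignmentError(
            f"{which} sequence contains letters outside the amino-acid "
            f"alphabet: {sorted(bad)}")


def align_global(ref_seq: str, tgt_seq: str,
                 matrix: Optional[substitution_matrices.Array] = None,
                 gap_open: float = -10.0,
                 gap_extend: float = -1.0) -> AlignmentResult:
    """Optimal end-to-end alignment under affine gap scoring.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``. The score is
    the maximum attainable over all global alignments; the traceback is
    deterministic.
    """
    ref_seq, tgt_seq = ref_seq.upper(), tgt_seq.upper()
    _check_sequence(ref_seq, "reference")
    _check_sequence(tgt_seq, "target")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix if matrix is not None else default_matrix()
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(ref_seq, tgt_seq)[0]
    ref_to_tgt: dict[int, Optional[int]] = {i: None
                                            for i in range(1, len(ref_seq) + 1)}
    for (r0, r1), (t0, t1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            ref_to_tgt[int(r0) + k + 1] = int(t0) + k + 1
    return AlignmentResult(aligned_ref=str(aln[0]), aligned_tgt=str(aln[1]),
                           score=float(aln.score), ref_to_tgt=ref_to_tgt)


def transfer_sites(alignment: AlignmentResult, ref_map: ResidueMap,
                   target_id: str,
                   ref_numbering: Callable[[int], int] = lambda i: i,
                   tgt_numbering: Callable[[int], int] = lambda i: i,
                   strict: bool = False) -> ResidueMap:
    """Carry site annotations from the reference to the aligned target.

    ``ref_numbering``/``tgt_numbering`` convert 1-based sequence indices to
    author residue numbers (identity by default). A reference entry aligned
    opposite a gap becomes unresolved; with ``strict=True`` an entry whose
    target amino acid differs from the reference's expected one is likewise
    dropped to "?" (off by default: pocket residues are genuinely
    non-identical across orthologs).
    """
    n_ref = len(alignment.ref_seq)
    author_to_index = {ref_numbering(i): i for i in range(1, n_ref + 1)}
    if len(author_to_index) != n_ref:
        raise AlignmentError("reference numbering is not injective")
    tgt_seq = alignment.tgt_seq

    new_sites: list[SiteDefinition] = []
    for site in ref_map.sites:
        entries: list[SiteEntry] = []
        for e in site.entries:
            if not e.resolved:
                entries.append(SiteEntry(e.chain_id, None, UNRESOLVED))
                continue
            i = author_to_index.get(e.number)
            if i is None:
                raise AlignmentError(
                    f"site {site.site_name}: reference residue {e.number} "
                    f"falls outside the aligned reference sequence")
            j = alignment.ref_to_tgt[i]
            if j is None:
                entries.append(SiteEntry(e.chain_id, None, UNRESOLVED))
                continue
            tgt_aa = tgt_seq[j - 1]
            if strict and tgt_aa != e.expected_aa:
                entries.append(SiteEntry(e.chain_id, None, UNRESOLVED))
                continue
            entries.append(SiteEntry(e.chain_id, tgt_numbering(j), tgt_aa))
        new_sites.append(SiteDefinition(site.site_name, entries))
    return ResidueMap(structure_id=target_id, sites=new_sites)


# --------------------------------------------------------------------------
# TSV site files
# --------------------------------------------------------------------------

_SITE_COLUMNS = ["structure_id", "site_name", "chain_id",
                 "residue_number", "expected_aa"]


def _load_sites_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteFileError(f"{path}: missing column(s) {missing}")
    unknown = set(df["site_name"]) - set(SITE_NAMES)
    if unknown:
        raise SiteFileError(f"{path}: unknown site name(s) {sorted(unknown)}")
    resolved = df[df["residue_number"] != UNRESOLVED]
    dup = resolved.duplicated(
        subset=["structure_id", "site_name", "chain_id", "residue_number"])
    if dup.any():
        rows = resolved[dup].to_dict("records")
        raise SiteFileError(f"{path}: duplicate site rows {rows}")
    return df


def _frame_to_map(df: pd.DataFrame, structure_id: str) -> ResidueMap:
    sites = []
    for name in SITE_NAMES:
        rows = df[df["site_name"] == name]
        if rows.empty:
            continue
        entries = []
        for _, row in rows.iterrows():
            if row["residue_number"] == UNRESOLVED:
                entries.append(SiteEntry(row["chain_id"], None, UNRESOLVED))
            else:
                try:
                    num = int(row["residue_number"])
                except ValueError:
                    raise SiteFileError(
                        f"bad residue_number {row['residue_number']!r} "
                        f"for {structure_id}/{name}") from None
                entries.append(SiteEntry(row["chain_id"], num,
                                         row["expected_aa"]))
        sites.append(SiteDefinition(name, entries))
    return ResidueMap(structure_id=structure_id, sites=sites)


def read_sites(path: str | Path,
               structure_id: Optional[str] = None) -> ResidueMap:
    """Read one structure's site definitions from a TSV file.

    When the file lists several structures, ``structure_id`` selects one
    (required in that case).
    """
    df = _load_sites_frame(path)
    ids = list(dict.fromkeys(df["structure_id"]))
    if structure_id is None:
        if len(ids) != 1:
            raise SiteFileError(
                f"{path} lists {len(ids)} structures {ids}; "
                f"pass structure_id to choose one")
        structure_id = ids[0]
    sub = df[df["structure_id"] == structure_id]
    if sub.empty:
        raise SiteFileError(f"{path}: no rows for structure {structure_id!r}")
    return _frame_to_map(sub, structure_id)


def read_all_sites(path: str | Path) -> dict[str, ResidueMap]:
    """Read every structure's site definitions from a TSV file."""
    df = _load_sites_frame(path)
    return {sid: _frame_to_map(df[df["structure_id"] == sid], sid)
            for sid in dict.fromkeys(df["structure_id"])}


def write_sites(rmap: ResidueMap, path: str | Path) -> None:
    rows = []
    for site in rmap.sites:
        for e in site.entries:
            rows.append({
                "structure_id": rmap.structure_id,
                "site_name": site.site_name,
                "chain_id": e.chain_id,
                "residue_number": str(e.number) if e.resolved else UNRESOLVED,
                "expected_aa": e.expected_aa,
            })
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def table1_sites_path() -> Path:
    """Path to the packaged functional-site table for the five insect
    Dicer-2 orthologs (reference crystal structure plus four homologs)."""
    return Path(resources.files("dicer_ruler") / "data" / "table1_sites.tsv")


# --------------------------------------------------------------------------
# Validation against a structure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Discrepancy:
    kind: str  # "absent_residue" | "identity_mismatch"
    site_name: str
    entry: SiteEntry
    detail: str


def validate_map(rmap: ResidueMap, structure: Structure) -> list[Discrepancy]:
    """Check that every resolved site entry exists in the structure with the
    expected amino acid. Returns discrepancies; never raises on content."""
    out: list[Discrepancy] = []
    index = structure.residue_index()
    for site in rmap.sites:
        for e in site.resolved_entries:
            res = index.get((e.chain_id, e.number, ""))
            if res is None:
                out.append(Discrepancy(
                    "absent_residue", site.site_name, e,
                    f"residue {e.chain_id}/{e.number} not in structure "
                    f"{structure.id!r}"))
            elif e.expected_aa not in (UNRESOLVED, res.aa_code):
                out.append(Discrepancy(
                    "identity_mismatch", site.site_name, e,
                    f"residue {e.chain_id}/{e.number} is {res.aa_code}, "
                    f"expected {e.expected_aa}"))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read amino-acid sequences from FASTA, keyed by record id."""
    records = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise SiteFileError(f"{path}: no FASTA records")
    return records
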