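"""Seeded generators of ground-truth test structures.

The homology models this analysis was designed for are not something a test
suite can fetch, so the package carries its own source of structures with
known geometry:

* **caliper scaffolds** — poly-alanine-style Cα traces containing four
  labelled residue clusters (the two PAZ pockets and the two RNase III
  catalytic centers) whose centroids sit at exactly the requested
  pocket<->center distances before noise, plus decoy residues for bulk.
  Optional isotropic Gaussian coordinate noise models rotamer/model
  variability; a seeded random rigid placement exercises frame invariance.
* **ideal A-form-like dsRNA duplexes** — two antiparallel strands of one
  phosphate-proxy pseudo-atom per nucleotide on a regular helix, for
  end-to-end geometry arithmetic (axial extent = (n_bp - 1) * rise).

Generation is fully deterministic given the spec (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .residue_map import ResidueMap, SiteDefinition, SiteEntry, SITE_NAMES
from .structure_io import Atom, Residue, Structure

__all__ = [
    "ScaffoldSpec",
    "DuplexSpec",
    "ScaffoldTruth",
    "generate_scaffold",
    "generate_duplex",
    "perturb",
]

#: Fixed author-numbering blocks for the four site clusters (chain A).
_SITE_NUMBER_BASE = {
    "RIII_A": 1200,
    "RIII_B": 1400,
    "pocket_3prime": 800,
    "pocket_5prime": 900,
}
#: Separation between the two RNase III centers in the scaffold (Å); the
#: tandem catalytic domains sit side by side in a dicing enzyme.
_CENTER_SEPARATION = 12.0


@dataclass
class ScaffoldSpec:
    structure_id: str
    d_3p_RIIIA: float  # target 3'-pocket <-> RNase III A distance, Å
    d_5p_RIIIB: float  # target 5'-pocket <-> RNase III B distance, Å
    residues_per_site: int = 4
    site_cluster_radius: float = 2.0  # Å
    noise_sigma: float = 0.0  # Å, Gaussian per coordinate
    seed: int = 0
    decoy_residues: int = 50

    def __post_init__(self) -> None:
        if self.residues_per_site < 1:
            raise ValueError("residues_per_site must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lim = 2.0 * self.site_cluster_radius
        if min(self.d_3p_RIIIA, self.d_5p_RIIIB) <= lim:
            raise ValueError(
                "geometrically infeasible spec: target distances must "
                f"exceed twice the cluster radius ({lim:.1f} Å)")


@dataclass
class DuplexSpec:
    n_bp: int
    rise: float = 2.81  # Å per base pair (A-form)
    twist: float = 32.7  # degrees per base pair (A-form)
    radius: float = 9.0  # Å, backbone radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("n_bp must be >= 2")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360) degrees")


@dataclass
class ScaffoldTruth:
    """Pre-noise ground truth accompanying a generated scaffold."""

    structure_id: str
    d_3p_RIIIA: float
    d_5p_RIIIB: float
    mean_distance: float
    seed: int
    noise_sigma: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _cluster(rng: np.random.Generator, center: np.ndarray, n: int,
             radius: float) -> np.ndarray:
    """n points whose mean is *exactly* center, spread within ~radius."""
    if n == 1:
        return center[None, :]
    offsets = rng.uniform(-radius, radius, size=(n, 3))
    offsets -= offsets.mean(axis=0)  # recenter -> centroid is exact
    return center[None, :] + offsets


def generate_scaffold(spec: ScaffoldSpec,
                      ) -> tuple[Structure, ResidueMap, ScaffoldTruth]:
    """Build a caliper scaffold with exactly the specified site-centroid
    distances (before noise), its matching residue map, and the ground
    truth. Noise (if any) is applied first, then a seeded random rigid
    placement."""
    rng = np.random.default_rng(spec.seed)

    # Site centers in a convenient local frame: the two catalytic centers on
    # one edge, each pocket at its target distance along x.
    centers = {
        "RIII_A": np.array([0.0, 0.0, 0.0]),
        "pocket_3prime": np.array([spec.d_3p_RIIIA, 0.0, 0.0]),
        "RIII_B": np.array([0.0, _CENTER_SEPARATION, 0.0]),
        "pocket_5prime": np.array([spec.d_5p_RIIIB, _CENTER_SEPARATION, 0.0]),
    }

    residues: list[Residue] = []
    sites: list[SiteDefinition] = []
    for name in SITE_NAMES:
        points = _cluster(rng, centers[name], spec.residues_per_site,
                          spec.site_cluster_radius)
        entries = []
        base = _SITE_NUMBER_BASE[name]
        for k, p in enumerate(points):
            number = base + k + 1
            residues.append(Residue(
                chain_id="A", number=number, aa_code="A",
                atoms=[Atom(name="CA", element="C", position=p.copy())]))
            entries.append(SiteEntry(chain_id="A", number=number,
                                     expected_aa="A"))
        sites.append(SiteDefinition(name, entries))

    # Decoy residues: bulk scattered around the scaffold's bounding box.
    span = max(spec.d_3p_RIIIA, spec.d_5p_RIIIB) + 10.0
    for k in range(spec.decoy_residues):
        p = rng.uniform([-10.0, -10.0, -span / 2],
                        [span, _CENTER_SEPARATION + 10.0, span / 2])
        residues.append(Residue(
            chain_id="A", number=k + 1, aa_code="A",
            atoms=[Atom(name="CA", element="C", position=p)]))

    if spec.noise_sigma > 0:
        for res in residues:
            for a in res.atoms:
                a.position = a.position + rng.normal(
                    0.0, spec.noise_sigma, size=3)

    # Random rigid placement (arbitrary frame; distances are invariant).
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50.0, 50.0, size=3)
    for res in residues:
        for a in res.atoms:
            a.position = R @ a.position + t

    residues.sort(key=lambda r: r.number)
    structure = Structure(id=spec.structure_id, residues=residues)
    rmap = ResidueMap(structure_id=spec.structure_id, sites=sites)
    truth = ScaffoldTruth(
        structure_id=spec.structure_id,
        d_3p_RIIIA=spec.d_3p_RIIIA,
        d_5p_RIIIB=spec.d_5p_RIIIB,
        mean_distance=(spec.d_3p_RIIIA + spec.d_5p_RIIIB) / 2.0,
        seed=spec.seed,
        noise_sigma=spec.noise_sigma,
    )
    return structure, rmap, truth


def generate_duplex(spec: DuplexSpec) -> Structure:
    """Ideal antiparallel duplex of phosphate-proxy pseudo-atoms.

    Strand I runs 5'->3' with residue i at helix level i-1; strand J is
    antiparallel (its residue 1 sits at the top level). One atom "P" per
    nucleotide; base pair levels are z = 0, rise, 2*rise, ...
    """
    twist = np.deg2rad(spec.twist)
    residues: list[Residue] = []
    for i in range(1, spec.n_bp + 1):
        level = i - 1
        angle = level * twist
        pos = np.array([spec.radius * np.cos(angle),
                        spec.radius * np.sin(angle),
                        level * spec.rise])
        residues.append(Residue(
            chain_id="I", number=i, aa_code="X", resname="RU",
            atoms=[Atom(name="P", element="P", position=pos)]))
    for j in range(1, spec.n_bp + 1):
        level = spec.n_bp - j  # antiparallel: residue 1 at the top
        angle = level * twist + np.pi
        pos = np.array([spec.radius * np.cos(angle),
                        spec.radius * np.sin(angle),
                        level * spec.rise])
        residues.append(Residue(
            chain_id="J", number=j, aa_code="X", resname="RU",
            atoms=[Atom(name="P", element="P", position=pos)]))
    return Structure(id=f"duplex_{spec.n_bp}bp", residues=residues)


def perturb(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Copy of the structure with i.i.d. Gaussian noise (sd sigma, Å) on
    every atom coordinate; deterministic for a given seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = structure.copy()
    if sigma == 0:
        return out
    for res in out.residues:
        for a in res.atoms:
            a.position = a.position + rng.normal(0.0, sigma, size=3)
    return out
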