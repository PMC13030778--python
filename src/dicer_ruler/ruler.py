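"""The molecular-ruler measurement: pocket-to-catalytic-center distances and
siRNA length-class prediction.

In a dicing enzyme the PAZ domain anchors the terminus of the dsRNA substrate
(distinct 3' and 5' pockets) while the two RNase III domains cleave the
duplex one strand each; the spatial separation between anchoring pockets and
catalytic centers acts as a caliper that sets the product length. This
module measures that caliper on a structure:

* site centers are unweighted centroids of designated residues' Cα atoms
  (side chains rotate freely, so Cα keeps the measure rotamer-independent;
  an all-heavy-atom policy is available for sensitivity checks);
* the ruler is the pair of Euclidean distances 3'-pocket <-> RNase III A and
  5'-pocket <-> RNase III B, summarized by their arithmetic mean;
* a calibration model converts mean distance to a nucleotide length class,
  either anchored to a reference enzyme of known product length (default:
  rise 2.0 Å per nucleotide) or by an ordinary least-squares line fitted to
  (distance, length) pairs.

All arithmetic is done at full precision; Å values are rounded to one
decimal only at serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_DOWN, Decimal
from typing import Optional, Sequence

import numpy as np

from .residue_map import ResidueMap, SiteDefinition, RULER_PAIRS
from .structure_io import Structure

__all__ = [
    "RulerMeasurement",
    "CalibrationModel",
    "LengthPrediction",
    "SiteResolutionError",
    "site_centroid",
    "site_centroid_detail",
    "measure_ruler",
    "replicate_stats",
    "fit_calibration",
    "predict_length",
    "relevance_flag",
    "round_half_away",
    "fmt_angstrom",
    "verify_reported_mean",
]

#: Product lengths a dicing enzyme plausibly produces (nt).
LENGTH_RANGE = (18, 24)
#: Spacing variations beyond this are treated as biologically relevant (Å).
RELEVANCE_THRESHOLD = 0.5
#: Default caliper pitch: Å of pocket-to-center distance per nucleotide of
#: product length. The crystallographic A-form helical rise (~2.81 Å/bp) is
#: an alternative; see the methods note.
DEFAULT_RISE = 2.0


class SiteResolutionError(LookupError):
    """A required site has no resolved entry present in the structure."""


@dataclass
class RulerMeasurement:
    """One structure's caliper: the two pocket<->center distances (Å)."""

    structure_id: str
    d_3p_RIIIA: float
    d_5p_RIIIB: float
    mean_distance: float
    sd: float = 0.0  # over replicates; 0 for a single run
    n_replicates: int = 1
    #: site_name -> number of unresolved ("?") or absent entries skipped
    skipped_entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.d_3p_RIIIA, self.d_5p_RIIIB) < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class CalibrationModel:
    """Converts a mean caliper distance into an siRNA length class."""

    d_ref: float  # Å, reference mean distance
    L_ref: int  # nt, product length of the reference enzyme
    rise: float = DEFAULT_RISE  # Å per nucleotide
    mode: str = "anchored_rounding"  # or "linear_fit"
    fit_slope: Optional[float] = None  # nt/Å
    fit_intercept: Optional[float] = None  # nt

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not LENGTH_RANGE[0] <= self.L_ref <= LENGTH_RANGE[1]:
            raise ValueError(
                f"L_ref {self.L_ref} outside the plausible siRNA range "
                f"{LENGTH_RANGE}")
        if self.mode not in ("anchored_rounding", "linear_fit"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.mode == "linear_fit" and (self.fit_slope is None
                                          or self.fit_intercept is None):
            raise ValueError("linear_fit mode needs fit_slope/fit_intercept")


@dataclass
class LengthPrediction:
    structure_id: str
    predicted_nt: int
    delta_vs_ref: float  # Å
    significant: bool
    in_range: bool = True  # False flags a prediction outside LENGTH_RANGE


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def fmt_angstrom(x: float) -> float:
    """Å value as serialized in reports: one decimal.

    The value is first quantized to 10^-3 Å — the coordinate precision of
    the PDB format, below which a distance carries no information — so that
    sub-precision noise cannot flip the displayed digit. The final decimal
    rounding resolves ties toward zero (58.35 -> 58.3), the convention the
    published distance table follows.
    """
    quantized = Decimal(repr(round(float(x), 3)))
    return float(quantized.quantize(Decimal("0.1"),
                                    rounding=ROUND_HALF_DOWN))


def site_centroid_detail(structure: Structure, site: SiteDefinition,
                         atom_policy: str = "calpha",
                         ) -> tuple[np.ndarray, int, int]:
    """Centroid of a site plus (n_used, n_skipped) bookkeeping.

    Unresolved ("?") entries and entries absent from the structure are
    skipped and counted; the centroid is the unweighted mean over the
    selected atoms of the remaining residues.
    """
    if atom_policy not in ("calpha", "all_heavy"):
        raise ValueError(f"unknown atom_policy {atom_policy!r}")
    index = structure.residue_index()
    coords: list[np.ndarray] = []
    skipped = site.unresolved_count
    for entry in site.resolved_entries:
        res = index.get((entry.chain_id, entry.number, ""))
        if res is None:
            skipped += 1
            continue
        if atom_policy == "calpha":
            atom = res.atom("CA")
            picked = [atom.position] if atom is not None else []
        else:
            picked = [a.position for a in res.atoms if a.element != "H"]
        if not picked:
            skipped += 1
            continue
        coords.extend(picked)
    if not coords:
        raise SiteResolutionError(
            f"site {site.site_name!r}: no resolved entries present in "
            f"structure {structure.id!r}")
    return np.mean(np.vstack(coords), axis=0), len(coords), skipped


def site_centroid(structure: Structure, site: SiteDefinition,
                  atom_policy: str = "calpha") -> np.ndarray:
    """Unweighted mean position (Å) of a site's designated atoms."""
    centroid, _used, _skipped = site_centroid_detail(structure, site,
                                                     atom_policy)
    return centroid


def measure_ruler(structure: Structure, rmap: ResidueMap,
                  atom_policy: str = "calpha") -> RulerMeasurement:
    """Measure the two pocket<->catalytic-center distances on a structure.

    Pairing convention: 3'-pocket with RNase III A, 5'-pocket with RNase
    III B. Raises :class:`SiteResolutionError` naming the first site that
    cannot be resolved.
    """
    centroids: dict[str, np.ndarray] = {}
    skipped: dict[str, int] = {}
    for pocket, center in RULER_PAIRS:
        for name in (pocket, center):
            if not rmap.has_site(name):
                raise SiteResolutionError(
                    f"map for {rmap.structure_id!r} lacks site {name!r}")
            c, _used, n_skip = site_centroid_detail(
                structure, rmap.site(name), atom_policy)
            centroids[name] = c
            if n_skip:
                skipped[name] = n_skip
    d1 = float(np.linalg.norm(centroids["pocket_3prime"]
                              - centroids["RIII_A"]))
    d2 = float(np.linalg.norm(centroids["pocket_5prime"]
                              - centroids["RIII_B"]))
    return RulerMeasurement(structure_id=structure.id, d_3p_RIIIA=d1,
                            d_5p_RIIIB=d2, mean_distance=(d1 + d2) / 2.0,
                            skipped_entries=skipped)


def replicate_stats(measurements: Sequence[RulerMeasurement],
                    ) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1; 0 when n=1) of the
    replicate mean distances."""
    if not measurements:
        raise ValueError("no measurements")
    values = np.array([m.mean_distance for m in measurements])
    if np.ptp(values) == 0:  # identical replicates: exactly zero spread
        return float(values[0]), 0.0
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return mean, sd


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least-squares line length = slope * distance + intercept.

    The fitted model's anchor is set to the centroid of the data: d_ref is
    the mean input distance and L_ref the (half-away-rounded) mean input
    length, so the anchor-consistency property holds for fitted models too.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    d = np.array([p[0] for p in points], dtype=float)
    L = np.array([p[1] for p in points], dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("degenerate fit: all calibration distances "
                         "are identical")
    slope, intercept = np.polyfit(d, L, 1)
    return CalibrationModel(
        d_ref=float(d.mean()),
        L_ref=round_half_away(float(L.mean())),
        rise=1.0 / float(slope),
        mode="linear_fit",
        fit_slope=float(slope),
        fit_intercept=float(intercept),
    )


def relevance_flag(delta: float, threshold: float = RELEVANCE_THRESHOLD,
                   ) -> bool:
    """True iff |delta| strictly exceeds the relevance threshold (Å)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return abs(delta) > threshold


def predict_length(mean_distance: float, model: CalibrationModel,
                   structure_id: str = "",
                   threshold: float = RELEVANCE_THRESHOLD,
                   ) -> LengthPrediction:
    """Convert a mean caliper distance (Å) into an siRNA length class (nt).

    anchored_rounding: L_ref + round((d - d_ref) / rise), nearest integer
    with ties away from zero. linear_fit: nearest integer of the fitted
    line. Predictions outside the plausible range are returned with
    ``in_range=False`` rather than raised.
    """
    if mean_distance <= 0:
        raise ValueError("mean_distance must be positive")
    if model.mode == "anchored_rounding":
        nt = model.L_ref + round_half_away(
            (mean_distance - model.d_ref) / model.rise)
    else:
        nt = round_half_away(model.fit_slope * mean_distance
                             + model.fit_intercept)
    delta = mean_distance - model.d_ref
    return LengthPrediction(
        structure_id=structure_id,
        predicted_nt=nt,
        delta_vs_ref=delta,
        significant=relevance_flag(delta, threshold),
        in_range=LENGTH_RANGE[0] <= nt <= LENGTH_RANGE[1],
    )


def verify_reported_mean(d_3p: float, d_5p: float, reported_mean: float,
                         ) -> tuple[float, bool]:
    """Recompute the mean of a distance pair and compare with a reported
    value at one-decimal precision.

    Returns (recomputed mean at full precision, matches). Used to flag
    internally inconsistent published rows instead of trusting them."""
    mean = (d_3p + d_5p) / 2.0
    return mean, fmt_angstrom(mean) == fmt_angstrom(reported_mean)
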