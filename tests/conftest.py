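from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pytest

from dicer_ruler import (ScaffoldSpec, generate_scaffold, write_sites,
                         write_structure)

# Published per-pocket distances (Å) and predominant siRNA length (nt) for
# the five insect Dicer-2 orthologs:
# structure_id -> (d 3'pocket<->RIII-A, d 5'pocket<->RIII-B,
#                  printed mean, printed length class)
TABLE2 = {
    "dmel": (61.0, 59.6, 60.3, 21),
    "tcas": (58.8, 61.2, 59.8, 21),  # printed mean is inconsistent: recomputed 60.0
    "bter": (61.7, 62.7, 62.2, 22),
    "lmig": (63.7, 60.9, 62.3, 22),
    "tni": (53.6, 63.1, 58.3, 20),
}


MINIMAL_PDB = textwrap.dedent("""\
    ATOM      1  N   GLU A1213      11.000  22.000  33.000  1.00 10.00           N
    ATOM      2  CA  GLU A1213      12.345  23.456  34.567  1.00 10.00           C
    END
    """)


@pytest.fixture
def minimal_pdb(tmp_path: Path) -> Path:
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260301)


def build_species_scaffold(species: str, seed: int = 0,
                           noise_sigma: float = 0.0):
    """Scaffold whose ruler geometry matches a published species row."""
    d3, d5, _mean, _nt = TABLE2[species]
    spec = ScaffoldSpec(structure_id=species, d_3p_RIIIA=d3, d_5p_RIIIB=d5,
                        noise_sigma=noise_sigma, seed=seed)
    return generate_scaffold(spec)


@pytest.fixture
def table2_workspace(tmp_path: Path) -> Path:
    """A pipeline workspace: one scaffold per published species row (exact
    geometry, no noise), per-structure site files, and a YAML config with
    the D. melanogaster scaffold as reference."""
    for i, species in enumerate(TABLE2):
        structure, rmap, _truth = build_species_scaffold(species, seed=100 + i)
        write_structure(structure, tmp_path / f"{species}.pdb")
        write_sites(rmap, tmp_path / f"{species}.sites.tsv")
    targets = "\n".join(
        f"  - id: {sp}\n"
        f"    structure: {sp}.pdb\n"
        f"    sites: {sp}.sites.tsv\n"
        f"    reported_mean: {TABLE2[sp][2]}\n"
        f"    reported_length: {TABLE2[sp][3]}"
        for sp in TABLE2 if sp != "dmel")
    config = textwrap.dedent("""\
        reference:
          id: dmel
          structure: dmel.pdb
          sites: dmel.sites.tsv
          L_ref: 21
        targets:
        {targets}
        rise: 2.0
        n_replicates: 3
        perturb_sigma: 0.0
        relevance_threshold: 0.5
        seed: 7
        """).format(targets=targets)
    (tmp_path / "config.yaml").write_text(config)
    return tmp_path
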