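"""Seeded synthetic-fixture generators with machine-readable ground truth.

Every generator returns its data plus a :class:`FixtureManifest` whose
ground-truth quantities are computed *at generation time* by independent
arithmetic (analytic formulas, brute-force predicates, exhaustive cuts) —
never by calling the module the fixture is meant to test.  A single master
seed fans out to per-generator child seeds by a stable hash derivation, so
fixture families are reproducible as a unit and byte-identical per seed.

The pocket fixture deserves a note.  A probe-difference detector assigns
zero pocket volume to any open bowl the envelope probe can roll into — for
an open hemisphere of radius r, probe centers with clearance >= 4 A reach
all the way to the bowl centre, so the whole bowl is envelope-accessible.
The generator therefore carves a buried *spherical* cavity reached through
a narrow cylindrical mouth channel: wide enough for the 1.4 A water probe,
too narrow for the 4.0 A envelope probe.  The analytic cavity volume is
(4/3) pi r^3 plus the channel cylinder (open) or (4/3) pi r^3 alone
(sealed, zero mouths), and the wall area is 4 pi r^2 (sealed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .structure import (
    POLAR_RESIDUES,
    STANDARD_RESIDUES,
    ProteinStructure,
    structure_from_arrays,
    vdw_radius,
    write_structure,
)

__all__ = [
    "FixtureManifest",
    "child_seed",
    "make_pocket_structure",
    "make_compound_table",
    "make_colony_data",
    "make_score_tables",
    "DEFAULT_DOSES",
    "IC50_ASSAY_DOSES",
]

#: Nine-point dose grid (uM) of the second-level colony formation screens.
DEFAULT_DOSES = (0.0061, 0.018, 0.05, 0.16, 0.49, 1.48, 4.44, 13.33, 40.0)

#: Dose grid (uM) of the melanoma IC50-determination assays, which brackets
#: a low-nanomolar IC50 on both sides (run with 3 replicates per dose).
IC50_ASSAY_DOSES = (0.001, 0.01, 0.1, 1.0, 10.0)

# pocket fixture geometry constants (A)
ATOM_ELEMENT = "C"
LATTICE_SPACING = 0.6
MOUTH_RADIUS = 2.4
MOUTH_DEPTH = 2.0  # channel length between surface plane and sphere top
WALL_THICKNESS = 4.0

_POLAR_LIST = sorted(POLAR_RESIDUES)
_APOLAR_LIST = sorted(STANDARD_RESIDUES - POLAR_RESIDUES)


def child_seed(master_seed: int, name: str) -> int:
    """Stable per-generator seed derived from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class FixtureManifest:
    generator: str
    seed: int
    parameters: dict
    ground_truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "parameters": self.parameters,
                "ground_truth": self.ground_truth,
            },
            indent=2,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _cavity_distance(
    points: np.ndarray,
    center: np.ndarray,
    radius: float,
    mouth_radius: float | None,
    z_low: float,
    z_high: float,
) -> np.ndarray:
    """Distance from each point to the cavity solid (sphere + channel)."""
    d_sphere = np.linalg.norm(points - center[None, :], axis=1) - radius
    if mouth_radius is None:
        return d_sphere
    rho = np.linalg.norm(points[:, :2], axis=1)
    dr = np.maximum(rho - mouth_radius, 0.0)
    dz = np.maximum.reduce(
        [z_low - points[:, 2], points[:, 2] - z_high, np.zeros(len(points))]
    )
    d_channel = np.hypot(dr, dz)
    return np.minimum(d_sphere, d_channel)


def make_pocket_structure(
    cavity_radius: float = 5.0,
    sealed: bool = False,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[ProteinStructure, FixtureManifest]:
    """Pseudo-protein slab with a cavity of known analytic volume.

    The slab is a cubic lattice of carbon pseudo-atoms (one single-atom
    residue each, names drawn from the 20 standard residues with a seeded
    split between polar and apolar).  A spherical cavity of
    ``cavity_radius`` is carved below the top face; unless ``sealed``, a
    cylindrical mouth channel (radius 2.4 A) connects it to the surface,
    giving exactly one mouth.  Atoms are kept when their centre clears the
    cavity solid by at least r_vdw - lattice/4, centring the bumpy wall on
    the analytic surface.

    If ``out_dir`` is given, writes ``pocket_fixture.pdb`` and
    ``pocket_fixture.manifest.json`` there (byte-identical per seed).
    """
    if not 3.0 <= cavity_radius <= 10.0:
        raise ValidationError(
            f"cavity_radius must be in [3, 10] A, got {cavity_radius}"
        )
    r = float(cavity_radius)
    r_atom = vdw_radius(ATOM_ELEMENT)
    half_width = r + WALL_THICKNESS
    depth = MOUTH_DEPTH + 2 * r + WALL_THICKNESS - 1.0
    center = np.array([0.0, 0.0, -(MOUTH_DEPTH + r)])

    xs = np.arange(-half_width, half_width + 1e-9, LATTICE_SPACING)
    zs = np.arange(-depth, 0.0 + 1e-9, LATTICE_SPACING)
    gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
    lattice = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    mouth = None if sealed else MOUTH_RADIUS
    dist = _cavity_distance(lattice, center, r, mouth, center[2], r_atom + 2.0)
    keep_threshold = r_atom - LATTICE_SPACING / 4.0
    coords = lattice[dist >= keep_threshold]

    rng = np.random.default_rng(seed)
    polar_mask = rng.random(len(coords)) < 0.5
    name_idx = rng.integers(0, max(len(_POLAR_LIST), len(_APOLAR_LIST)), len(coords))
    residue_names = [
        (_POLAR_LIST if polar else _APOLAR_LIST)[
            idx % (len(_POLAR_LIST) if polar else len(_APOLAR_LIST))
        ]
        for polar, idx in zip(polar_mask, name_idx)
    ]
    structure = structure_from_arrays(
        coords,
        [ATOM_ELEMENT] * len(coords),
        residue_names,
        structure_id=f"pocket-fixture-r{r:g}-{'sealed' if sealed else 'open'}",
    )

    sphere_volume = 4.0 / 3.0 * math.pi * r**3
    channel_volume = (
        0.0 if sealed else math.pi * MOUTH_RADIUS**2 * (MOUTH_DEPTH + r_atom)
    )
    lining = _cavity_distance(coords, center, r, mouth, center[2], r_atom + 2.0) < (
        r_atom + 1.0
    )
    manifest = FixtureManifest(
        generator="make_pocket_structure",
        seed=seed,
        parameters={
            "cavity_radius": r,
            "sealed": sealed,
            "lattice_spacing": LATTICE_SPACING,
            "mouth_radius": None if sealed else MOUTH_RADIUS,
            "mouth_depth": None if sealed else MOUTH_DEPTH,
            "n_atoms": int(len(coords)),
        },
        ground_truth={
            "cavity_volume": sphere_volume + channel_volume,
            "sphere_volume": sphere_volume,
            "channel_volume": channel_volume,
            "wall_area_sphere": 4.0 * math.pi * r**2,
            "mouth_count": 0 if sealed else 1,
            "cavity_center": center.tolist(),
            "n_polar_residues": int(polar_mask.sum()),
            "n_lining_polar_residues": int((polar_mask & lining).sum()),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_structure(structure, out_dir / "pocket_fixture.pdb")
        manifest.save(out_dir / "pocket_fixture.manifest.json")
    return structure, manifest


def make_compound_table(
    n: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, FixtureManifest]:
    """Compound property table straddling all four drug-likeness thresholds.

    MW ~ N(320, 120) truncated at 1, TPSA ~ |N(110, 40)|, HBD ~ Pois(2.5),
    HBA ~ Pois(5).  The manifest records the exact survivor ids of the
    standard window (MW in [160, 480], TPSA < 140, HBD < 5, HBA < 10),
    evaluated by an inline predicate at generation time.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mw = np.maximum(rng.normal(320.0, 120.0, n), 1.0).round(2)
    tpsa = np.abs(rng.normal(110.0, 40.0, n)).round(2)
    hbd = rng.poisson(2.5, n)
    hba = rng.poisson(5.0, n)
    ids = [f"CMPD-{i:05d}" for i in range(1, n + 1)]
    df = pd.DataFrame(
        {
            "compound_id": ids,
            "smiles": ["*" for _ in ids],  # opaque placeholder
            "mw": mw,
            "tpsa": tpsa,
            "hbd": hbd,
            "hba": hba,
        }
    )
    survivors = [
        cid
        for cid, m, t, d, a in zip(ids, mw, tpsa, hbd, hba)
        if 160.0 <= m <= 480.0 and t < 140.0 and d < 5 and a < 10
    ]
    manifest = FixtureManifest(
        generator="make_compound_table",
        seed=seed,
        parameters={"n": n},
        ground_truth={
            "survivor_count": len(survivors),
            "survivor_ids": survivors,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "compounds.csv", index=False)
        manifest.save(out_dir / "compounds.manifest.json")
    return df, manifest


def make_colony_data(
    params: dict | None = None,
    cv: float = 0.1,
    replicates: int = 2,
    seed: int = 0,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    cell_line: str = "M14",
    compound: str = "CMPD-1",
    control_mean: float = 200.0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, FixtureManifest]:
    """Colony counts on a known 4PL curve with multiplicative noise.

    ``params`` holds the truth (bottom/top in % of control, ic50 in uM,
    hill); counts are control_mean * 4PL(dose)/100 * LogNormal(mean 1, cv),
    rounded to integers, with zero-dose control rows included.
    """
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    truth = {"bottom": 0.0, "top": 100.0, "ic50": 0.012, "hill": -1.0}
    if params:
        truth.update(params)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    def noise() -> float:
        if sigma == 0.0:
            return 1.0
        return float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))

    def curve(dose: float) -> float:
        if dose == 0.0:
            return 100.0
        exponent = (math.log10(truth["ic50"]) - math.log10(dose)) * truth["hill"]
        return truth["bottom"] + (truth["top"] - truth["bottom"]) / (
            1.0 + 10.0**exponent
        )

    rows = []
    for dose in (0.0, *doses):
        for rep in range(1, replicates + 1):
            expected = control_mean * curve(dose) / 100.0
            rows.append(
                {
                    "cell_line": cell_line,
                    "compound": compound,
                    "concentration_uM": dose,
                    "day": 8,
                    "replicate": rep,
                    "colonies": int(round(expected * noise())),
                }
            )
    df = pd.DataFrame(rows)
    manifest = FixtureManifest(
        generator="make_colony_data",
        seed=seed,
        parameters={
            "cv": cv,
            "replicates": replicates,
            "doses": list(doses),
            "control_mean": control_mean,
        },
        ground_truth=dict(truth),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "colonies.csv", index=False)
        manifest.save(out_dir / "colonies.manifest.json")
    return df, manifest


def make_score_tables(
    n_compounds: int,
    stages: int = 3,
    seed: int = 0,
    keeps: tuple[float | int, ...] | None = None,
    final_k: int = 100,
    out_dir: str | Path | None = None,
) -> tuple[list[pd.DataFrame], FixtureManifest]:
    """Per-stage score tables with planted rank correlation.

    A latent compound quality drives every stage's score (plus independent
    noise), so top ranks correlate across stages.  The manifest records the
    brute-force survivor list of every stage for the default keep schedule
    (fraction 0.25, then 0.5 per later stage), computed by exhaustive
    sort-and-slice with the (score, id) tie policy.
    """
    if stages < 1:
        raise ValidationError("stages must be >= 1")
    if n_compounds < 1:
        raise ValidationError("n_compounds must be >= 1")
    if keeps is None:
        keeps = (0.25,) + (0.5,) * (stages - 1)
    if len(keeps) != stages:
        raise ValidationError(f"{len(keeps)} keeps for {stages} stages")
    rng = np.random.default_rng(seed)
    ids = [f"CMPD-{i:05d}" for i in range(1, n_compounds + 1)]
    quality = rng.normal(0.0, 1.0, n_compounds)
    tables: list[pd.DataFrame] = []
    scores_per_stage: list[dict[str, float]] = []
    for s in range(stages):
        score = -quality + rng.normal(0.0, 0.6, n_compounds)
        entries = {cid: float(v) for cid, v in zip(ids, np.round(score, 6))}
        scores_per_stage.append(entries)
        tables.append(
            pd.DataFrame(
                {"compound_id": ids, "score": [entries[c] for c in ids]}
            )
        )

    # exhaustive survivor computation, independent of the funnel module
    survivors_per_stage: list[list[str]] = []
    pool = list(ids)
    for s, keep in enumerate(keeps):
        ordered = sorted(pool, key=lambda c: (scores_per_stage[s][c], c))
        if isinstance(keep, float) and keep < 1:
            k = max(1, math.ceil(keep * len(ordered)))
        else:
            k = int(keep)
        pool = ordered[:k]
        survivors_per_stage.append(list(pool))
    final = survivors_per_stage[-1][:final_k]

    manifest = FixtureManifest(
        generator="make_score_tables",
        seed=seed,
        parameters={
            "n_compounds": n_compounds,
            "stages": stages,
            "keeps": list(keeps),
            "final_k": final_k,
        },
        ground_truth={
            "survivors_per_stage": survivors_per_stage,
            "final_ranking": final,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s, table in enumerate(tables, start=1):
            table.to_csv(out_dir / f"stage{s}.csv", index=False)
        manifest.save(out_dir / "scores.manifest.json")
    return tables, manifest
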