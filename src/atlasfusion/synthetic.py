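"""Synthetic cohorts for validating the pipeline end to end.

Three generators emulate the data the pipeline consumes:

* **fractional Gaussian noise** (fGn) with a known Hurst exponent, via exact
  circulant embedding (Davies-Harte) of the theoretical autocovariance
  ``gamma(k) = 0.5 (|k+1|^{2h} - 2|k|^{2h} + |k-1|^{2h})`` -- the ground-truth
  oracle for the R/S estimator;
* **image-space cohorts**: per-subject 4D BOLD-like volumes whose voxel
  series are fGn with group-dependent h in planted regions, plus modulated
  GM-like maps with planted regional atrophy, on toy lattice atlases small
  enough for tests to run in seconds;
* **feature tables** with a planted mean shift of standardized size d in an
  equicorrelated informative block, for selection and classification tests.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas import AtlasDefinition
from .selection import FeatureTable, make_feature_name

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "simulate_fgn",
    "fgn_autocovariance",
    "make_lattice_atlas",
    "simulate_cohort",
    "simulate_feature_table",
]


def fgn_autocovariance(h: float, lags: np.ndarray) -> np.ndarray:
    """Theoretical autocovariance of unit-variance fGn at the given lags."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_fgn(h: float, n: int, seed=None) -> np.ndarray:
    """Sample a length-``n`` unit-variance fGn series with Hurst exponent ``h``.

    Uses Davies-Harte circulant embedding, which reproduces the theoretical
    autocovariance exactly in expectation.  In the rare small-n case where the
    circulant spectrum is not non-negative, falls back to a Cholesky factor of
    the exact covariance (logged).
    """
    if not 0.0 < h < 1.0:
        raise ValueError("h must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = _rng(seed)
    gamma = fgn_autocovariance(h, np.arange(n + 1))
    circ = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-9 * lam.max():
        logger.warning(
            "circulant embedding not non-negative definite at n=%d, h=%.3f; "
            "falling back to Cholesky",
            n,
            h,
        )
        from scipy.linalg import cholesky, toeplitz

        cov = toeplitz(gamma[:n])
        return cholesky(cov, lower=True) @ rng.standard_normal(n)
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    w = np.empty(m, dtype=complex)
    normals = rng.standard_normal(m)
    w[0] = np.sqrt(lam[0] / m) * normals[0]
    w[n] = np.sqrt(lam[n] / m) * normals[1]
    u = normals[2 : n + 1]
    v = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u + 1j * v)
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    return np.fft.fft(w).real[:n]


def make_lattice_atlas(
    shape: tuple = (12, 12, 12),
    blocks: tuple = (2, 2, 2),
    voxel_mm: float = 3.0,
    name: str = "lattice",
) -> AtlasDefinition:
    """Toy parcellation: an axis-aligned lattice of equal-size blocks.

    A (12, 12, 12) grid with (2, 2, 2) blocks yields 8 regions of 6x6x6
    voxels each, labelled 1..8 in C order.
    """
    labels = np.zeros(shape, dtype=int)
    edges = [np.linspace(0, s, b + 1).astype(int) for s, b in zip(shape, blocks)]
    region = 1
    for i in range(blocks[0]):
        for j in range(blocks[1]):
            for k in range(blocks[2]):
                labels[
                    edges[0][i] : edges[0][i + 1],
                    edges[1][j] : edges[1][j + 1],
                    edges[2][k] : edges[2][k + 1],
                ] = region
                region += 1
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return AtlasDefinition(
        name=name,
        labels=labels,
        affine=affine,
        region_ids=np.arange(1, region),
    )


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group cohort.

    Defaults mirror a small MCI-vs-HC study: balanced groups, a moderate
    planted atrophy/persistence contrast in a few regions, 229 retained
    volumes at TR = 2 s.
    """

    n_positive: int = 20
    n_negative: int = 20
    effect_regions: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"GMV": [1, 2], "HE": [3, 4]}
    )
    effect_size: float = 1.0
    h_by_group: tuple = (0.7, 0.5)  # (patients, controls) in affected regions
    h_background: float = 0.5
    feature_correlation: float = 0.0
    n_timepoints: int = 229
    tr_seconds: float = 2.0
    gm_baseline: float = 0.6
    gm_voxel_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size d must be non-negative")
        for h in (*self.h_by_group, self.h_background):
            if not 0.0 < h < 1.0:
                raise ValueError("Hurst exponents must lie in (0, 1)")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature correlation must lie in [0, 1)")
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both groups need at least one subject")


@dataclass
class SyntheticCohort:
    """Simulated image-space cohort: one 4D series + GM map per subject."""

    bold: list
    gm_maps: list
    labels: np.ndarray
    atlas: AtlasDefinition
    spec: CohortSpec


def simulate_cohort(
    spec: CohortSpec,
    atlas: AtlasDefinition,
    modalities: Sequence[str] = ("HE", "GMV"),
) -> SyntheticCohort:
    """Generate per-subject 4D BOLD-like volumes and modulated-GM-like maps.

    Voxel series are independent fGn: Hurst exponent ``h_by_group[group]`` in
    the HE effect regions, ``h_background`` elsewhere.  GM maps are voxelwise
    Gaussian around ``gm_baseline``; in the GMV effect regions the patient
    group mean is shifted down by ``effect_size * gm_voxel_sd`` (atrophy).
    Restricting ``modalities`` skips the other modality's (expensive)
    generation; its per-subject list is then empty.
    """
    for modality, regions in spec.effect_regions.items():
        unknown = set(int(r) for r in regions) - set(atlas.region_ids.tolist())
        if unknown:
            raise ValueError(f"unknown region id(s) for {modality}: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    labels = np.concatenate(
        [np.ones(spec.n_positive, dtype=int), np.zeros(spec.n_negative, dtype=int)]
    )
    he_regions = set(int(r) for r in spec.effect_regions.get("HE", []))
    gmv_regions = set(int(r) for r in spec.effect_regions.get("GMV", []))
    he_mask = np.isin(atlas.labels, list(he_regions)) if he_regions else np.zeros_like(atlas.labels, bool)
    gmv_mask = np.isin(atlas.labels, list(gmv_regions)) if gmv_regions else np.zeros_like(atlas.labels, bool)
    shape = atlas.labels.shape
    n_voxels = int(np.prod(shape))
    bold, gm_maps = [], []
    flat_affected = he_mask.ravel()
    for label in labels:
        if "HE" in modalities:
            h_affected = spec.h_by_group[0] if label == 1 else spec.h_by_group[1]
            series = np.empty((n_voxels, spec.n_timepoints))
            for row, h in (
                (np.where(flat_affected)[0], h_affected),
                (np.where(~flat_affected)[0], spec.h_background),
            ):
                for v in row:
                    series[v] = simulate_fgn(h, spec.n_timepoints, rng)
            bold.append(series.reshape(*shape, spec.n_timepoints))
        if "GMV" in modalities:
            gm = spec.gm_baseline + spec.gm_voxel_sd * rng.standard_normal(shape)
            if label == 1:
                gm[gmv_mask] -= spec.effect_size * spec.gm_voxel_sd
            gm_maps.append(np.clip(gm, 0.0, None))
    return SyntheticCohort(bold=bold, gm_maps=gm_maps, labels=labels, atlas=atlas, spec=spec)


def simulate_feature_table(
    spec: CohortSpec,
    n_features: int = 16,
    n_informative: int = 3,
    modality: str = "SIM",
    atlas_name: str = "sim",
) -> FeatureTable:
    """Gaussian subject x feature table with a planted group effect.

    The first ``n_informative`` columns form the informative block: patient
    rows are mean-shifted by ``effect_size`` (features have unit variance) and
    block members share pairwise correlation ``feature_correlation``.  The
    remaining columns are independent noise.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positive + spec.n_negative
    labels = np.concatenate(
        [np.ones(spec.n_positive, dtype=int), np.zeros(spec.n_negative, dtype=int)]
    )
    values = rng.standard_normal((n, n_features))
    rho = spec.feature_correlation
    if n_informative and rho > 0:
        shared = rng.standard_normal(n)
        values[:, :n_informative] = (
            np.sqrt(rho) * shared[:, None]
            + np.sqrt(1 - rho) * values[:, :n_informative]
        )
    if n_informative:
        values[labels == 1, :n_informative] += spec.effect_size
    names = [
        make_feature_name(atlas_name, modality, f"region_{j + 1}") for j in range(n_features)
    ]
    meta = [(modality, atlas_name, f"region_{j + 1}") for j in range(n_features)]
    return FeatureTable(
        values=values, labels=labels, feature_names=names, feature_meta=meta
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write a simulated cohort as NIfTI images + CSV labels; return paths."""
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = cohort.atlas.affine
    atlas_path = out / "atlas.nii"
    nib.save(nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), affine), str(atlas_path))
    rows = []
    for i, (series, gm, label) in enumerate(
        zip(cohort.bold, cohort.gm_maps, cohort.labels)
    ):
        sid = f"sub-{i:03d}"
        bold_path = out / f"{sid}_bold.nii"
        gm_path = out / f"{sid}_gm.nii"
        nib.save(nib.Nifti1Image(series.astype(np.float32), affine), str(bold_path))
        nib.save(nib.Nifti1Image(gm.astype(np.float32), affine), str(gm_path))
        rows.append(
            {"subject_id": sid, "label": int(label), "bold": bold_path.name, "gm": gm_path.name}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "subjects.csv", index=False)
    return {
        "atlas": atlas_path,
        "subjects": out / "subjects.csv",
        "tr_seconds": cohort.spec.tr_seconds,
    }
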