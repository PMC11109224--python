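"""Synthetic inputs with known ground truth for every pipeline stage.

Real biobank CINEs, genotypes, and summary statistics cannot ship with the
package, so each consumer has a generator that emulates its input at the
study's stated acquisition conditions:

* sliced geometric phantoms (sphere / ellipsoid / two-lobe) rasterized
  onto the standard view plan — three long-axis planes 60 degrees apart
  about the long axis plus a six-slice short-axis stack — with analytic
  volume as ground truth;
* 8-channel chamber-area filling curves with or without an atrial kick;
* lead-SNP tables with a known number of distance-separated clusters, and
  reference lists planted to overlap a chosen subset of them;
* two-sample MR instrument sets with a stated causal effect, optional
  balanced or directional pleiotropy, and sample-size-driven noise.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats

from .plane_geometry import CineSegmentation, PlaneGeometry
from .surface_reconstruction import VolumeTrace

N_FRAMES = 50
LAX_SPACING_MM = 1.83
SAX_SPACING_MM = 1.86
SAX_THICKNESS_MM = 8.0
SAX_GAP_MM = 2.0


def _orthonormal_frame(long_axis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = np.asarray(long_axis, float)
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return u, e1, e2


@dataclass
class PhantomSpec:
    """A time-varying convex phantom and the view plan used to slice it."""

    shape: str = "sphere"  # sphere | ellipsoid | two_lobe
    semi_axes_mm: tuple | Callable[[int], tuple] = (30.0, 30.0, 30.0)
    center_mm: tuple = (0.0, 0.0, 0.0)
    long_axis: tuple = (0.0, 0.0, 1.0)
    lobe_offset_mm: float = 80.0  # two_lobe: centre-to-centre distance
    lobe_scale: float = 0.5  # two_lobe: second lobe semi-axis ratio
    n_frames: int = N_FRAMES
    lax_angles_deg: tuple = (0.0, 60.0, 120.0)
    n_sax_slices: int = 6
    sax_thickness_mm: float = SAX_THICKNESS_MM
    sax_gap_mm: float = SAX_GAP_MM
    image_size: int = 96
    lax_spacing_mm: float = LAX_SPACING_MM
    sax_spacing_mm: float = SAX_SPACING_MM
    include_sax: bool = True
    jitter_px: float = 0.0  # boundary pixel-flip noise
    seed: int = 0

    def axes_at(self, t: int) -> np.ndarray:
        axes = self.semi_axes_mm(t) if callable(self.semi_axes_mm) else self.semi_axes_mm
        axes = np.asarray(axes, float)
        if np.any(axes <= 0):
            raise ValueError(f"semi-axes must be positive (frame {t})")
        return axes

    def analytic_volume_ml(self, t: int) -> float:
        axes = self.axes_at(t)
        v = 4.0 / 3.0 * np.pi * float(np.prod(axes))
        if self.shape == "two_lobe":
            v = v * (1.0 + self.lobe_scale**3)
        return v / 1000.0


def pulsating_radius(r0_mm: float = 25.0, amp_mm: float = 5.0, n_frames: int = N_FRAMES):
    """r(t) = r0 + amp*sin(2*pi*t/T): a breathing sphere's semi-axes."""

    def axes(t: int) -> tuple:
        r = r0_mm + amp_mm * np.sin(2.0 * np.pi * t / n_frames)
        return (r, r, r)

    return axes


def _inside(points: np.ndarray, spec: PhantomSpec, t: int) -> np.ndarray:
    u, e1, e2 = _orthonormal_frame(spec.long_axis)
    basis = np.stack([u, e1, e2])  # local frame rows
    axes = spec.axes_at(t)
    rel = (points - np.asarray(spec.center_mm)) @ basis.T
    inside = np.sum((rel / axes) ** 2, axis=1) <= 1.0
    if spec.shape == "two_lobe":
        center2 = np.asarray(spec.center_mm) + spec.lobe_offset_mm * u
        rel2 = (points - center2) @ basis.T
        inside |= np.sum((rel2 / (axes * spec.lobe_scale)) ** 2, axis=1) <= 1.0
    return inside


def _plane_grid(geom: PlaneGeometry, size: int) -> np.ndarray:
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    from .plane_geometry import pixel_to_patient

    return pixel_to_patient(rows.ravel(), cols.ravel(), geom)


def _jitter_mask(mask: np.ndarray, jitter_px: float, rng: np.random.Generator) -> np.ndarray:
    """Flip boundary pixels in or out to emulate segmentation noise."""
    if jitter_px <= 0 or mask.sum() == 0:
        return mask
    p = min(0.5, jitter_px / 2.0)
    inner = mask.astype(bool) & ~ndimage.binary_erosion(mask.astype(bool))
    outer = ndimage.binary_dilation(mask.astype(bool)) & ~mask.astype(bool)
    out = mask.astype(bool).copy()
    out[inner & (rng.random(mask.shape) < p)] = False
    out[outer & (rng.random(mask.shape) < p)] = True
    return out.astype(np.uint8)


def _plane_geometry(center, d_col, d_row, spacing, size, thickness=0.0) -> PlaneGeometry:
    half = (size - 1) / 2.0 * spacing
    origin = np.asarray(center, float) - half * d_col - half * d_row
    return PlaneGeometry(
        origin_mm=origin,
        row_cosine=d_col,
        col_cosine=d_row,
        spacing_mm=(spacing, spacing),
        thickness_mm=thickness,
    )


def make_phantom(spec: PhantomSpec) -> tuple[list[CineSegmentation], VolumeTrace]:
    """Rasterize the phantom on every view plane and frame.

    Returns the per-view CINEs (with geometry sidecar information) and the
    analytic ground-truth volume trace in mL.  A plane that misses the
    shape in every frame still emits (empty) masks, with a warning.
    """
    import logging

    rng = np.random.default_rng(spec.seed)
    u, e1, e2 = _orthonormal_frame(spec.long_axis)
    center = np.asarray(spec.center_mm, float)

    plan: list[tuple[str, PlaneGeometry]] = []
    for angle in spec.lax_angles_deg:
        phi = np.deg2rad(angle)
        d1 = np.cos(phi) * e1 + np.sin(phi) * e2
        geom = _plane_geometry(center, d1, u, spec.lax_spacing_mm, spec.image_size, 6.0)
        plan.append((f"lax_{angle:g}", geom))
    if spec.include_sax:
        spacing_between = spec.sax_thickness_mm + spec.sax_gap_mm
        for j in range(spec.n_sax_slices):
            offset = (j - (spec.n_sax_slices - 1) / 2.0) * spacing_between
            geom = _plane_geometry(
                center + offset * u, e1, e2, spec.sax_spacing_mm, spec.image_size,
                spec.sax_thickness_mm,
            )
            plan.append((f"sax_{j}", geom))

    views = []
    for label, geom in plan:
        pts = _plane_grid(geom, spec.image_size)
        frames = np.empty((spec.n_frames, spec.image_size, spec.image_size), np.uint8)
        for t in range(spec.n_frames):
            mask = _inside(pts, spec, t).reshape(spec.image_size, spec.image_size)
            frames[t] = _jitter_mask(mask.astype(np.uint8), spec.jitter_px, rng)
        if frames.sum() == 0:
            logging.getLogger(__name__).warning(
                "plane %s misses the phantom in every frame", label
            )
        views.append(CineSegmentation(frames=frames, geometry=geom, view=label))

    truth = VolumeTrace(
        volumes_ml=np.array([spec.analytic_volume_ml(t) for t in range(spec.n_frames)])
    )
    return views, truth


# ---------------------------------------------------------------------------
# Filling curves


def make_filling_curves(
    kick: bool = True, noise_sd: float = 0.0, seed: int = 0, n_frames: int = N_FRAMES
) -> tuple[dict, str]:
    """Plausible 8-channel chamber-area curves over one cardiac cycle.

    Atrial channels fill during ventricular systole and empty afterwards;
    with ``kick`` a late-cycle contraction dip is added, whose absence
    emulates the filling pattern seen with atrial fibrillation.
    ``noise_sd`` is the relative SD of multiplicative pixel-count noise.
    Returns (channel dict, label) with label in {"normal", "abnormal"}.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / n_frames
    atrial = 0.55 - 0.35 * np.cos(2 * np.pi * t)
    if kick:
        atrial = atrial - 0.30 * np.exp(-0.5 * ((t - 0.88) / 0.03) ** 2)
    ventricular = 0.55 + 0.35 * np.cos(2 * np.pi * t)
    scales = {
        "lax_4ch_la": 1500, "lax_4ch_ra": 1300, "lax_4ch_lv": 2500, "lax_4ch_rv": 2600,
        "lax_3ch_la": 1200, "lax_3ch_lv": 2400,
        "lax_2ch_la": 1400, "lax_2ch_lv": 2500,
    }
    curves = {}
    for name, scale in scales.items():
        base = atrial if name.endswith("_la") or name.endswith("_ra") else ventricular
        series = scale * base
        if noise_sd > 0:
            series = series * (1.0 + noise_sd * rng.standard_normal(n_frames))
        curves[name] = np.maximum(np.round(series), 1.0)
    return curves, ("normal" if kick else "abnormal")


# ---------------------------------------------------------------------------
# Lead-SNP tables

_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_MAX_CHROM_BP = 240_000_000


def make_leadsnp_table(
    n_clusters: int,
    snps_per_cluster: int = 2,
    intra_span_kb: int = 100,
    inter_gap_kb: int = 2000,
    seed: int = 0,
    trait: str = "synthetic",
) -> pd.DataFrame:
    """Lead-SNP table whose 500-kb merge yields exactly ``n_clusters`` loci.

    Clusters are laid round-robin across chromosomes 1-22; SNPs inside a
    cluster span at most ``intra_span_kb`` while cluster anchors are
    ``inter_gap_kb`` apart (both must be consistent with the merge window
    the caller will use).
    """
    if intra_span_kb >= inter_gap_kb:
        raise ValueError("intra-cluster span must be smaller than the inter-cluster gap")
    rng = np.random.default_rng(seed)
    per_chrom = -(-n_clusters // 22)
    stride = (inter_gap_kb + intra_span_kb) * 1000
    if 1_000_000 + per_chrom * stride > _MAX_CHROM_BP:
        raise ValueError("requested spacing does not fit on 22 chromosomes")
    rows = []
    for i in range(n_clusters):
        chrom = str(i % 22 + 1)
        anchor = 1_000_000 + (i // 22) * stride
        offsets = rng.integers(0, intra_span_kb * 1000 + 1, size=snps_per_cluster)
        offsets[0] = 0
        for j, off in enumerate(offsets):
            ea, oa = _NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))]
            rows.append(
                {
                    "trait": trait,
                    "chr": chrom,
                    "bp": int(anchor + off),
                    "rsid": f"snp_{i}_{j}",
                    "ea": ea,
                    "oa": oa,
                    "eaf": float(rng.uniform(0.05, 0.95)),
                    "beta": float(rng.normal(0, 0.05)),
                    "se": 0.007,
                    "p": float(10 ** rng.uniform(-12, -8)),
                }
            )
    return pd.DataFrame(rows)


def make_reference_leads(
    table: pd.DataFrame,
    n_overlapping: int,
    n_background: int = 10,
    offset_kb: int = 100,
    window_kb: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference lead list overlapping exactly ``n_overlapping`` loci.

    Overlapping references sit ``offset_kb`` from the first
    ``n_overlapping`` locus leads of ``table``; background references are
    planted far beyond every cluster.
    """
    from .loci_overlap import merge_loci

    rng = np.random.default_rng(seed)
    loci = merge_loci(table, window_kb=window_kb).loci
    if n_overlapping > len(loci):
        raise ValueError("cannot overlap more loci than the table defines")
    rows = []
    for loc in loci[:n_overlapping]:
        rows.append({"trait": "reference", "chr": loc.chrom,
                     "bp": loc.lead_bp + offset_kb * 1000,
                     "rsid": f"ref_{loc.chrom}_{loc.lead_bp}",
                     "ea": "A", "oa": "G", "eaf": 0.5, "beta": 0.1,
                     "se": 0.01, "p": 1e-9})
    for b in range(n_background):
        rows.append({"trait": "reference", "chr": str(rng.integers(1, 23)),
                     "bp": int(200_000_000 + b * 1_500_000),
                     "rsid": f"bg_{b}", "ea": "A", "oa": "G", "eaf": 0.5,
                     "beta": 0.1, "se": 0.01, "p": 1e-9})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-sample MR datasets


@dataclass
class MRSimSpec:
    """Generative settings for a two-sample MR summary-statistic pair."""

    k: int = 50
    theta: float = 0.5
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_scale: float = 0.0
    inside_violation: bool = False
    n_exposure: int = 300_000
    n_outcome: int = 300_000
    beta_exp_mean: float = 0.08
    beta_exp_sd: float = 0.02
    palindromic_frac: float = 0.0
    swap_frac: float = 0.3  # outcome rows reported on the flipped allele
    seed: int = 0

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("need at least 3 instruments")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")


def make_mr_dataset(spec: MRSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome summary tables with known causal effect.

    True per-SNP exposure effects are drawn around ``beta_exp_mean`` with
    random sign; standard errors follow 1/sqrt(2 n f (1-f)).  Outcome betas
    are theta * beta plus the chosen pleiotropy term plus noise.  Under an
    InSIDE violation, directional pleiotropy is made proportional to
    instrument strength.  A configurable fraction of variants is
    palindromic and a fraction of outcome rows is reported on the swapped
    allele, to exercise harmonization.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    eaf = rng.uniform(0.1, 0.9, size=k)
    se_x = 1.0 / np.sqrt(2.0 * spec.n_exposure * eaf * (1 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * spec.n_outcome * eaf * (1 - eaf))
    sign = rng.choice([-1.0, 1.0], size=k)
    true_bx = sign * rng.normal(spec.beta_exp_mean, spec.beta_exp_sd, size=k)
    if spec.pleiotropy == "none":
        alpha = np.zeros(k)
    elif spec.pleiotropy == "balanced":
        alpha = rng.normal(0.0, spec.pleiotropy_scale, size=k)
    else:
        # directional pleiotropy is defined on the exposure-increasing allele,
        # so align the direct effect with each instrument's sign
        alpha = sign * spec.pleiotropy_scale
        if spec.inside_violation:
            alpha = spec.pleiotropy_scale * true_bx / spec.beta_exp_mean
    obs_bx = true_bx + rng.normal(0.0, se_x)
    obs_by = spec.theta * true_bx + alpha + rng.normal(0.0, se_y)

    n_pal = int(round(spec.palindromic_frac * k))
    pal_idx = rng.choice(k, size=n_pal, replace=False)
    alleles = []
    for i in range(k):
        pool = _PALINDROMIC if i in pal_idx else _NON_PALINDROMIC
        alleles.append(pool[rng.integers(len(pool))])

    rows_exp, rows_out = [], []
    for i in range(k):
        chrom = str(i % 22 + 1)
        bp = 1_000_000 + (i // 22) * 20_000_000
        ea, oa = alleles[i]
        p = float(2 * sp_stats.norm.sf(abs(obs_bx[i] / se_x[i])))
        rows_exp.append({"trait": "exposure", "chr": chrom, "bp": bp,
                         "rsid": f"iv_{i}", "ea": ea, "oa": oa,
                         "eaf": float(eaf[i]), "beta": float(obs_bx[i]),
                         "se": float(se_x[i]), "p": max(p, 1e-300)})
        swap = rng.random() < spec.swap_frac
        rows_out.append({"trait": "outcome", "chr": chrom, "bp": bp,
                         "rsid": f"iv_{i}",
                         "ea": oa if swap else ea, "oa": ea if swap else oa,
                         "eaf": float(1 - eaf[i] if swap else eaf[i]),
                         "beta": float(-obs_by[i] if swap else obs_by[i]),
                         "se": float(se_y[i]), "p": 0.5})
    return pd.DataFrame(rows_exp), pd.DataFrame(rows_out)
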