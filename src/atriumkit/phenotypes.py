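"""Left-atrial phenotypes from volume traces, plus the filling-curve tensor.

The four scalar phenotypes are the maximum and minimum LA volume over the
cardiac cycle (LAmax, LAmin), their difference (stroke volume, LASV), and
the emptying fraction LAEF = LASV / LAmax.  Each may be indexed to body
surface area.  The 50 x 8 filling-curve tensor is the per-chamber pixel
count over the cycle, self-normalized per channel, used as input to
filling-pattern classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface_reconstruction import VolumeTrace

#: fixed channel order of the filling tensor
FILLING_CHANNELS = (
    "lax_4ch_la",
    "lax_4ch_ra",
    "lax_4ch_lv",
    "lax_4ch_rv",
    "lax_3ch_la",
    "lax_3ch_lv",
    "lax_2ch_la",
    "lax_2ch_lv",
)


class IncompleteTraceError(ValueError):
    pass


class ChannelExclusionError(ValueError):
    """A study must provide all 8 non-degenerate channels or be excluded."""


@dataclass(frozen=True)
class LAPhenotypes:
    la_max_ml: float
    la_min_ml: float
    la_sv_ml: float
    la_ef_frac: float
    bsa_m2: float | None = None
    la_max_i: float | None = None
    la_min_i: float | None = None
    la_sv_i: float | None = None


@dataclass
class FillingCurveTensor:
    values: np.ndarray  # 50 x 8 in [0, 1]
    channels: tuple = FILLING_CHANNELS


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m^2 (Du Bois by default, Mosteller optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "dubois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    raise ValueError(f"unknown BSA formula: {formula!r}")


def la_phenotypes(trace: VolumeTrace, bsa_m2: float | None = None) -> LAPhenotypes:
    """Scalar LA phenotypes from a complete volume trace."""
    if not trace.complete:
        raise IncompleteTraceError(
            "trace has missing frames; phenotypes require a complete reconstruction"
        )
    v = trace.volumes_ml
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    la_max = float(v.max())
    la_min = float(v.min())
    la_sv = la_max - la_min
    if la_max <= 0:
        raise ZeroDivisionError("LAEF is undefined when LAmax is zero")
    la_ef = la_sv / la_max
    indexed = {}
    if bsa_m2 is not None:
        if bsa_m2 <= 0:
            raise ValueError("BSA must be positive")
        indexed = {
            "bsa_m2": bsa_m2,
            "la_max_i": la_max / bsa_m2,
            "la_min_i": la_min / bsa_m2,
            "la_sv_i": la_sv / bsa_m2,
        }
    return LAPhenotypes(
        la_max_ml=la_max, la_min_ml=la_min, la_sv_ml=la_sv, la_ef_frac=la_ef, **indexed
    )


def filling_tensor(area_curves: dict) -> FillingCurveTensor:
    """Self-normalized 50 x 8 filling tensor from per-chamber pixel counts.

    ``area_curves`` maps each channel name in :data:`FILLING_CHANNELS` to a
    length-50 series of pixel counts.  Each channel is divided by its own
    maximum, so the tensor encodes relative size change only.  Studies
    missing any channel, or with a zero-maximum channel, are excluded.
    """
    missing = [c for c in FILLING_CHANNELS if c not in area_curves]
    if missing:
        raise ChannelExclusionError(f"missing channel(s): {missing}; all 8 required")
    cols = []
    n = None
    for c in FILLING_CHANNELS:
        series = np.asarray(area_curves[c], float)
        if n is None:
            n = len(series)
        elif len(series) != n:
            raise ValueError("all channels must share the same length")
        m = series.max()
        if m <= 0:
            raise ChannelExclusionError(f"channel {c} has zero maximum")
        cols.append(series / m)
    return FillingCurveTensor(values=np.column_stack(cols))


def classify_filling_pattern(tensor: FillingCurveTensor, min_kick_frac: float = 0.05) -> str:
    """Reference heuristic filling-pattern classifier (not a trained model).

    The pluggable classifier interface maps a filling tensor to "normal" or
    "abnormal".  This built-in stand-in checks for an atrial-kick dip: a
    local minimum of the mean LA channel inside the final quarter of the
    cycle, followed by a rebound of at least ``min_kick_frac`` of the
    channel's range.  Passive emptying alone only falls monotonically, so
    it does not qualify.  A trained time-series model can be dropped in
    anywhere a callable with this signature is accepted.
    """
    la_idx = [i for i, c in enumerate(tensor.channels) if c.endswith("_la")]
    v = tensor.values[:, la_idx].mean(axis=1)
    rng = max(v.max() - v.min(), 1e-12)
    tail = v[int(0.75 * len(v)):]
    i_min = int(tail.argmin())
    rebound = tail[i_min:].max() - tail[i_min] if i_min < len(tail) - 1 else 0.0
    return "normal" if rebound >= min_kick_frac * rng else "abnormal"


def phenotype_row(study_id: str, pheno: LAPhenotypes) -> dict:
    """Flat record matching the phenotype TSV schema."""
    return {
        "id": study_id,
        "la_max_ml": pheno.la_max_ml,
        "la_min_ml": pheno.la_min_ml,
        "la_sv_ml": pheno.la_sv_ml,
        "la_ef": pheno.la_ef_frac,
        "bsa_m2": pheno.bsa_m2,
        "la_max_i": pheno.la_max_i,
        "la_min_i": pheno.la_min_i,
        "la_sv_i": pheno.la_sv_i,
    }
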