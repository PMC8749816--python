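"""Diffusion-approximation light transport between diffuser-fiber pairs.

The transmitted 635 nm treatment light between an emitting and a detecting
cylindrical diffuser fiber is modelled in the diffusion approximation of the
radiative transfer equation.  Each active section is a linear array of
isotropic point sources/detectors (five per mm, equal weights); the fluence a
point source produces at distance r in a homogeneous medium is the standard
point-source Green's function

    Phi(r) = 3 (mu_a + mu_s') / (4 pi r) * exp(-mu_eff r),
    mu_eff = sqrt(3 mu_a (mu_a + mu_s')),

with absorption coefficient ``mu_a`` and reduced scattering coefficient
``mu_s'`` (held at 2 mm^-1 throughout).  The theoretically expected pair
intensity is

    I_t,theo = P0 * (L_E / N) * sum_ij Phi(r_ij),

where ``L_E`` is the emitting diffuser length in cm, ``N`` the number of
point combinations and ``P0`` (cm * counts/ms) a setup calibration factor
fitted on tissue phantoms.  Inverting a per-pair lookup table I_t,theo(mu_a)
against the measured intensity yields a volume-averaged ``mu_a`` for the
tissue between the pair; the change during therapy is ``delta mu_a``.

At 635 nm blood is the dominant absorber, so forward scenarios express
``mu_a`` through the blood volume fraction (bvf) and the hemoglobin species
mix (HbO2 / Hb / MetHb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import CDFPair, parallel_pair

__all__ = [
    "OpticalProperties",
    "LookupTable",
    "MU_A_HBO2",
    "MU_A_HB",
    "MU_A_METHB",
    "CAPILLARY_SATURATION",
    "CAPILLARY_FRACTIONS",
    "DEFAULT_MU_S_PRIME",
    "DETECTION_THRESHOLD_NORMALIZED",
    "LOOKUP_GRID",
    "mu_eff",
    "point_fluence",
    "pair_transmission",
    "hemoglobin_mua",
    "transmission_curve",
    "build_lookup",
    "invert_mua",
    "min_mua_for_threshold",
    "delta_mua",
    "mua_post_from_ratio",
    "fit_P0",
]

#: Absorption coefficients of pure hemoglobin species at 635 nm (mm^-1).
MU_A_HBO2 = 0.2477
MU_A_HB = 2.1149
MU_A_METHB = 8.1073

#: Assumed oxygen saturation of normal capillary blood.
CAPILLARY_SATURATION = 0.85
#: Species mix of normal capillary blood (85% HbO2 / 15% Hb).
CAPILLARY_FRACTIONS = {"HbO2": CAPILLARY_SATURATION, "Hb": 1.0 - CAPILLARY_SATURATION}

_SPECIES = {"HbO2": MU_A_HBO2, "Hb": MU_A_HB, "MetHb": MU_A_METHB}

#: Reduced scattering coefficient held constant in all inversions (mm^-1).
DEFAULT_MU_S_PRIME = 2.0

#: Empirical detection threshold of the monitoring setup, normalized to the
#: transmission of a 20 mm pair at 10 mm separation in tumor-like tissue.
DETECTION_THRESHOLD_NORMALIZED = 1.9e-4

#: mu_a lookup grid: 0.0001 to 0.75 mm^-1 at 0.0001 mm^-1 resolution.
LOOKUP_GRID = (1e-4, 0.75, 1e-4)


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous tissue optical properties at 635 nm (mm^-1)."""

    mu_a: float
    mu_s_prime: float = DEFAULT_MU_S_PRIME

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be non-negative")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s' must be positive")

    @property
    def mu_eff(self) -> float:
        return mu_eff(self.mu_a, self.mu_s_prime)


def mu_eff(mu_a, mu_s_prime=DEFAULT_MU_S_PRIME):
    """Effective attenuation coefficient sqrt(3 mu_a (mu_a + mu_s'))."""
    return np.sqrt(3.0 * np.asarray(mu_a) * (np.asarray(mu_a) + mu_s_prime))


def point_fluence(r, props: OpticalProperties):
    """Point-source diffusion fluence per emitted photon at distance r (mm).

    Strictly decreasing in both r and mu_a; r = 0 is a singularity.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("point_fluence requires r > 0 (point-source singularity)")
    pref = 3.0 * (props.mu_a + props.mu_s_prime) / (4.0 * np.pi * r)
    return pref * np.exp(-props.mu_eff * r)


def _double_sum(distances: np.ndarray, mu_a_values: np.ndarray, mu_s_prime: float) -> np.ndarray:
    """sum_ij Phi(r_ij) for each mu_a, vectorized and chunked over the grid."""
    r = distances.ravel()
    inv_r = 1.0 / r
    atten = mu_eff(mu_a_values, mu_s_prime)
    pref = 3.0 * (mu_a_values + mu_s_prime) / (4.0 * np.pi)
    out = np.empty(mu_a_values.size)
    chunk = max(1, int(4e6 // r.size))
    for start in range(0, mu_a_values.size, chunk):
        sl = slice(start, start + chunk)
        out[sl] = pref[sl] * (np.exp(-np.outer(atten[sl], r)) @ inv_r)
    return out


def pair_transmission(pair: CDFPair, props: OpticalProperties, p0: float = 1.0) -> float:
    """Theoretical transmitted intensity I_t,theo for one ordered pair.

    ``p0`` is the calibration factor in cm * counts/ms; the emitting diffuser
    length enters in cm (the single unit conversion from the mm-based
    geometry).  The result does not depend on the detector diffuser length
    beyond its discretization (homogeneous-detection assumption).
    """
    if pair.min_distance <= 0.0:
        raise ValueError("emitter and detector points coincide (singular geometry)")
    total = _double_sum(pair.distances, np.array([props.mu_a]), props.mu_s_prime)[0]
    le_cm = pair.emitter.length_mm / 10.0
    return float(p0 * le_cm / pair.n_combinations * total)


def hemoglobin_mua(bvf_percent: float, fractions: dict | None = None) -> float:
    """Tissue absorption at 635 nm from blood content alone.

    ``mu_a = (bvf/100) * sum_s fraction_s * mu_a,s`` over the hemoglobin
    species; all other chromophores are neglected.  The default species mix is
    normal capillary blood (85% HbO2, 15% Hb).
    """
    if not 0.0 <= bvf_percent <= 100.0:
        raise ValueError("bvf must be between 0 and 100 percent")
    if fractions is None:
        fractions = CAPILLARY_FRACTIONS
    unknown = set(fractions) - set(_SPECIES)
    if unknown:
        raise ValueError(f"unknown hemoglobin species: {sorted(unknown)}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"species fractions sum to {total:g}, expected 1")
    return bvf_percent / 100.0 * sum(f * _SPECIES[s] for s, f in fractions.items())


def transmission_curve(
    mu_a_values,
    distances_mm,
    length_mm: float = 20.0,
    mu_s_prime: float = DEFAULT_MU_S_PRIME,
    reference: tuple[float, float] = (0.02, 10.0),
) -> np.ndarray:
    """Normalized transmission versus distance for a family of mu_a values.

    Returns an array of shape ``(len(mu_a_values), len(distances_mm))``,
    normalized to the intensity at the reference ``(mu_a, distance)`` -- by
    default tumor-like tissue (0.02 mm^-1) at 10 mm.  The calibration factor
    and emitter power cancel in the normalization.
    """
    mu_a_values = np.atleast_1d(np.asarray(mu_a_values, dtype=float))
    distances_mm = np.atleast_1d(np.asarray(distances_mm, dtype=float))
    ref_pair = parallel_pair(reference[1], length_mm)
    ref = pair_transmission(ref_pair, OpticalProperties(reference[0], mu_s_prime))
    if ref <= 0:
        raise ValueError("reference intensity must be positive")
    out = np.empty((mu_a_values.size, distances_mm.size))
    for j, d in enumerate(distances_mm):
        pair = parallel_pair(float(d), length_mm)
        sums = _double_sum(pair.distances, mu_a_values, mu_s_prime)
        out[:, j] = (length_mm / 10.0) / pair.n_combinations * sums / ref
    return out


# ---------------------------------------------------------------------------
# lookup table inversion
# ---------------------------------------------------------------------------


@dataclass
class LookupTable:
    """Per-pair lookup of I_t,theo over the standard mu_a grid.

    Intensities are strictly decreasing in mu_a, which makes nearest-intensity
    matching equivalent to bisection.
    """

    mu_a: np.ndarray
    intensity: np.ndarray
    mu_s_prime: float = DEFAULT_MU_S_PRIME
    p0: float = 1.0
    pair_id: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.intensity) >= 0):
            raise ValueError("lookup intensities must be strictly decreasing in mu_a")

    def invert(self, i_t: float) -> float:
        return invert_mua(i_t, self)

    def threshold_mua(self, threshold_intensity: float) -> float:
        return min_mua_for_threshold(threshold_intensity, self)


def build_lookup(
    pair: CDFPair,
    mu_s_prime: float = DEFAULT_MU_S_PRIME,
    p0: float = 1.0,
    grid: tuple[float, float, float] = LOOKUP_GRID,
) -> LookupTable:
    """Tabulate I_t,theo(mu_a) for one pair over the standard inversion grid."""
    lo, hi, step = grid
    n = int(round((hi - lo) / step)) + 1
    mu_a_values = lo + step * np.arange(n)
    sums = _double_sum(pair.distances, mu_a_values, mu_s_prime)
    le_cm = pair.emitter.length_mm / 10.0
    intensity = p0 * le_cm / pair.n_combinations * sums
    return LookupTable(
        mu_a=mu_a_values, intensity=intensity, mu_s_prime=mu_s_prime, p0=p0, pair_id=pair.pair_id
    )


def invert_mua(i_t: float, table: LookupTable) -> float:
    """Grid mu_a whose tabulated intensity best matches the measured I_t.

    Ties break toward smaller mu_a.  Intensities outside the table's range are
    clipped to the nearest end with a warning; non-positive intensities are an
    input error (use :func:`min_mua_for_threshold` for non-detections).
    """
    if i_t <= 0:
        raise ValueError("measured intensity must be positive; for undetectable "
                         "signals use min_mua_for_threshold")
    if i_t > table.intensity[0]:
        warnings.warn("measured intensity above table range; clipping to the smallest mu_a")
        return float(table.mu_a[0])
    if i_t < table.intensity[-1]:
        warnings.warn("measured intensity below table range; clipping to the largest mu_a")
        return float(table.mu_a[-1])
    k = int(np.argmin(np.abs(table.intensity - i_t)))
    return float(table.mu_a[k])


def min_mua_for_threshold(threshold_intensity: float, table: LookupTable) -> float:
    """Smallest grid mu_a with tabulated intensity at or below the threshold.

    This is the minimum absorption able to explain a non-detection: any
    smaller mu_a would have produced a detectable signal.
    """
    if threshold_intensity <= 0:
        raise ValueError("threshold intensity must be positive")
    if threshold_intensity > table.intensity[0]:
        raise ValueError(
            "threshold exceeds the table's maximum intensity: no mu_a can "
            "explain a non-detection for this pair"
        )
    if threshold_intensity < table.intensity[-1]:
        warnings.warn("threshold below table minimum; mu_a saturates at the grid maximum")
        return float(table.mu_a[-1])
    k = int(np.searchsorted(-table.intensity, -threshold_intensity))
    return float(table.mu_a[k])


def delta_mua(
    mu_a_pre: float | None,
    mu_a_post: float | None,
    pre_qualifier: str = "measured",
    post_qualifier: str = "measured",
) -> tuple[float, str]:
    """Absorption change delta mu_a = mu_a,post - mu_a,pre with a qualifier.

    Pairs without detectable pre-iPDT transmission have no defined change
    (returns ``(nan, "undefined")``).  When the post value is itself a
    detection-threshold lower bound, the difference is a lower bound too.
    """
    if pre_qualifier in ("undetectable", "lower-bound") or mu_a_pre is None:
        return float("nan"), "undefined"
    if mu_a_post is None:
        return float("nan"), "undefined"
    value = float(mu_a_post - mu_a_pre)
    if post_qualifier == "lower-bound":
        return value, "lower-bound"
    return value, "measured"


def mua_post_from_ratio(mu_a_pre: float, ratio: float, table: LookupTable) -> float:
    """Post-iPDT mu_a from the transmission ratio, without absolute calibration.

    Solves I_t,theo(mu_a_post) = I_t,theo(mu_a_pre) / R on the lookup table,
    anchored at a supplied pre-iPDT mu_a.  Used when the calibration factor of
    a case is unknown (e.g. a deviating detection filter) but the ratio R is
    still trustworthy, since P0 cancels.
    """
    if ratio <= 0:
        raise ValueError("transmission ratio must be positive")
    i_pre = float(np.interp(mu_a_pre, table.mu_a, table.intensity))
    return invert_mua(i_pre / ratio, table)


def fit_P0(measurements) -> tuple[float, float]:
    """Calibration factor P0 from phantom measurements with known properties.

    ``measurements`` is an iterable of records (mapping or object) with fields
    ``distance_mm``, ``emitter_length_mm``, ``detector_length_mm``, ``mu_a``,
    ``mu_s_prime`` and ``intensity`` -- parallel-pair phantom geometries.  P0
    is the least-squares scalar of intensity = P0 * model; returns
    ``(P0, residual norm)``.
    """
    records = list(measurements)
    if len(records) == 0:
        raise ValueError("no phantom measurements supplied")

    def get(rec, key):
        return rec[key] if isinstance(rec, dict) else getattr(rec, key)

    model = np.empty(len(records))
    observed = np.empty(len(records))
    distances = set()
    for k, rec in enumerate(records):
        d = float(get(rec, "distance_mm"))
        distances.add(round(d, 6))
        pair = parallel_pair(d, float(get(rec, "emitter_length_mm")),
                             float(get(rec, "detector_length_mm")))
        props = OpticalProperties(float(get(rec, "mu_a")), float(get(rec, "mu_s_prime")))
        model[k] = pair_transmission(pair, props, p0=1.0)
        observed[k] = float(get(rec, "intensity"))
    if len(records) == 1:
        warnings.warn("single phantom measurement: exact ratio solution, no redundancy")
    elif len(records) < 3 or len(distances) < 2:
        warnings.warn("phantom set is weakly constrained (need >= 3 measurements "
                      "spanning >= 2 distances)")
    p0 = float(model @ observed / (model @ model))
    residual = float(np.linalg.norm(observed - p0 * model))
    return p0, residual
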