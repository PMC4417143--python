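"""Power-law normalization of CAGE tag counts.

Across CAGE libraries the reverse cumulative distribution of tags per TSS is
close to a power law: on log10-log10 axes the number of TSSs with count >= v
falls on a line of slope -alpha.  Normalization exploits this by fitting the
per-sample law within a count range, choosing a shared reference law
(slope alpha_ref, total tag count T), and mapping each sample's counts onto
the reference so that all samples share one distribution.  Tags-per-million
scaling and a raw pass-through are provided for workflows that prefer them.

The reference intercept follows from the requirement that the reference
distribution hold T tags in total:  sum_{x>=1} 10^beta x^(-alpha) =
10^beta * zeta(alpha) = T, hence beta_ref = log10(T / zeta(alpha_ref)),
which needs alpha_ref > 1 for the zeta series to converge.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import zeta

from .ctss import CtssTable

DEFAULT_FIT_RANGE = (10, 1000)


@dataclasses.dataclass
class PowerLawFit:
    """Log-log OLS fit of one sample's reverse-cumulative count distribution.

    ``alpha`` is the magnitude of the fitted slope, ``beta`` the log10
    intercept; the fit used ``n_points`` distinct count values within
    [fit_min, fit_max].
    """

    alpha: float
    beta: float
    fit_min: float
    fit_max: float
    n_points: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("power-law slope magnitude must be positive")
        if self.n_points < 2:
            raise ValueError("fit needs at least 2 points")


@dataclasses.dataclass
class ReferenceLaw:
    alpha: float
    total: float
    beta: float = None  # derived when omitted

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError(
                f"reference slope {self.alpha} <= 1 implies an infinite total")
        if self.total <= 0:
            raise ValueError("reference total must be positive")
        derived = float(np.log10(self.total / zeta(self.alpha)))
        if self.beta is None:
            self.beta = derived
        elif abs(self.beta - derived) > 1e-9:
            raise ValueError("beta inconsistent with log10(T / zeta(alpha))")


def reverse_cumulative(counts) -> np.ndarray:
    """Return (value, number of items >= value) pairs, one per distinct value.

    Values ascend; the tail count r is strictly decreasing; r at the
    smallest value equals the number of items.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("reverse_cumulative of empty input")
    values, freq = np.unique(counts, return_counts=True)
    r = freq[::-1].cumsum()[::-1]
    return np.column_stack([values, r.astype(float)])


def fit_power_law(revcum: np.ndarray, fit_min: float = DEFAULT_FIT_RANGE[0],
                  fit_max: float = DEFAULT_FIT_RANGE[1],
                  sample_id: str = "") -> PowerLawFit:
    """OLS on (log10 v, log10 r(v)) restricted to fit_min <= v <= fit_max.

    One point per distinct count value, so long plateaus of identical counts
    do not dominate the fit.
    """
    revcum = np.asarray(revcum, dtype=float)
    m = (revcum[:, 0] >= fit_min) & (revcum[:, 0] <= fit_max)
    pts = revcum[m]
    if len(pts) < 2:
        raise ValueError(
            f"power-law fit needs >= 2 distinct counts in [{fit_min}, {fit_max}]; "
            f"got {len(pts)}")
    slope, intercept = np.polyfit(np.log10(pts[:, 0]), np.log10(pts[:, 1]), 1)
    return PowerLawFit(alpha=float(-slope), beta=float(intercept),
                       fit_min=fit_min, fit_max=fit_max, n_points=len(pts),
                       sample_id=sample_id)


def choose_reference(fits, library_sizes) -> ReferenceLaw:
    """Median slope across samples; total = power of 10 nearest the median depth."""
    fits = list(fits)
    if not fits:
        raise ValueError("choose_reference needs at least one fit")
    alpha_ref = float(np.median([f.alpha for f in fits]))
    depth = float(np.median(np.asarray(list(library_sizes), dtype=float)))
    if depth <= 0:
        raise ValueError("median library size must be positive")
    T_ref = 10.0 ** round(np.log10(depth))
    return ReferenceLaw(alpha=alpha_ref, total=T_ref)


def powerlaw_map(x, fit: PowerLawFit, ref: ReferenceLaw) -> np.ndarray:
    """Map raw counts x onto the reference law.

    Solves r_sample(x) = r_ref(x') for x':
    x' = (10^beta_s x^(-alpha_s) / 10^beta_ref)^(-1/alpha_ref), a strictly
    increasing transform, so within-sample ranks are preserved.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = 10.0 ** ((fit.beta - ref.beta) / ref.alpha) \
        * x[pos] ** (fit.alpha / ref.alpha)
    return out


def normalize_powerlaw(table: CtssTable, fits: dict, ref: ReferenceLaw,
                       round_to_int: bool = False) -> CtssTable:
    """Normalize every sample of a CtssTable to the common reference law."""
    missing = [s for s in table.sample_ids if s not in fits]
    if missing:
        raise ValueError(f"no power-law fit for sample(s) {missing}")
    mat = np.column_stack([
        powerlaw_map(table.data[s].to_numpy(), fits[s], ref)
        for s in table.sample_ids]) if len(table) else np.empty((0, len(table.sample_ids)))
    if round_to_int:
        mat = np.round(mat)
    return table.with_signal(mat, normalized=True)


def normalize_tpm(table: CtssTable) -> CtssTable:
    """Scale each sample to tags per million of its library size."""
    for s in table.sample_ids:
        if table.library_sizes.get(s, 0) <= 0:
            raise ValueError(f"zero library size for sample {s!r}")
    mat = np.column_stack([
        table.data[s].to_numpy() / table.library_sizes[s] * 1e6
        for s in table.sample_ids]) if len(table) else np.empty((0, len(table.sample_ids)))
    return table.with_signal(mat, normalized=True)


def fit_all_samples(table: CtssTable, fit_min: float = DEFAULT_FIT_RANGE[0],
                    fit_max: float = DEFAULT_FIT_RANGE[1]) -> dict:
    """Reverse-cumulative power-law fit for every sample of a table."""
    fits = {}
    for s in table.sample_ids:
        counts = table.data[s].to_numpy()
        rc = reverse_cumulative(counts[counts > 0])
        fits[s] = fit_power_law(rc, fit_min, fit_max, sample_id=s)
    return fits
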