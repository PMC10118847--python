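"""CDR3 length spectratyping with Gaussian goodness-of-fit.

A polyclonal repertoire shows an approximately Gaussian CDR3 length
distribution; clonal expansions concentrate abundance at the lengths of the
dominant clones and degrade the fit.  The fit statistic is the coefficient
of determination R² = 1 − SS_res/SS_tot of a least-squares Gaussian curve

    a · exp(−(x − μ)² / (2σ²))

through the relative-abundance histogram.  R² of a nonlinear fit can be
negative; values are reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyRepertoireError, FitError, InsufficientSupportError
from .io import PRODUCTIVE, RepertoireSample


@dataclass
class LengthHistogram:
    """Relative abundance of CDR3 lengths (nt or aa), zero bins included
    inside the observed range."""

    unit: str  # "nt" | "aa"
    lengths: np.ndarray  # increasing integers
    rel_abundance: np.ndarray  # sums to 1
    weighting: str  # "templates" | "unique"


@dataclass
class SpectratypeFit:
    amplitude: float
    mean: float
    sd: float
    r_squared: float


def length_distribution(
    sample: RepertoireSample, unit: str = "aa", weighting: str = "templates"
) -> LengthHistogram:
    """CDR3 length histogram of the productive subset of a sample."""
    if unit not in ("nt", "aa"):
        raise ValueError(f"unknown unit {unit!r}")
    if weighting not in ("templates", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    prod = [r for r in sample.rearrangements if r.frame_status == PRODUCTIVE]
    if not prod:
        raise EmptyRepertoireError(
            f"sample {sample.sample_id!r} has no productive rearrangements"
        )
    weights: dict[int, float] = {}
    for r in prod:
        length = len(r.cdr3_nt) if unit == "nt" else len(r.cdr3_nt) // 3
        w = r.template_count if weighting == "templates" else 1
        weights[length] = weights.get(length, 0.0) + w
    lo, hi = min(weights), max(weights)
    step = 3 if unit == "nt" else 1
    lengths = np.arange(lo, hi + 1, step)
    abundance = np.array([weights.get(int(l), 0.0) for l in lengths])
    return LengthHistogram(
        unit=unit,
        lengths=lengths,
        rel_abundance=abundance / abundance.sum(),
        weighting=weighting,
    )


def average_histograms(hists: list[LengthHistogram]) -> LengthHistogram:
    """Mean relative-abundance histogram over samples (group-level curve).

    Histograms are aligned on the union of their length ranges, with zeros
    where a sample has no mass, then averaged bin-wise.
    """
    if not hists:
        raise ValueError("no histograms to average")
    units = {h.unit for h in hists}
    if len(units) != 1:
        raise ValueError(f"mixed units {units}")
    unit = hists[0].unit
    step = 3 if unit == "nt" else 1
    lo = min(int(h.lengths.min()) for h in hists)
    hi = max(int(h.lengths.max()) for h in hists)
    lengths = np.arange(lo, hi + 1, step)
    acc = np.zeros(len(lengths))
    for h in hists:
        lookup = dict(zip(h.lengths.tolist(), h.rel_abundance.tolist()))
        acc += np.array([lookup.get(int(l), 0.0) for l in lengths])
    return LengthHistogram(
        unit=unit,
        lengths=lengths,
        rel_abundance=acc / len(hists),
        weighting=hists[0].weighting,
    )


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(hist: LengthHistogram) -> SpectratypeFit:
    """Least-squares Gaussian fit to a length histogram.

    Initialisation is deterministic: amplitude = max bin, μ = abundance-
    weighted mean, σ = abundance-weighted SD (floored to half a bin).
    """
    x = hist.lengths.astype(float)
    y = hist.rel_abundance.astype(float)
    if len(x) < 3:
        raise InsufficientSupportError(
            f"need >= 3 distinct lengths to fit a Gaussian, got {len(x)}"
        )
    a0 = float(y.max())
    mu0 = float((x * y).sum() / y.sum())
    sd0 = float(np.sqrt(((x - mu0) ** 2 * y).sum() / y.sum()))
    step = float(x[1] - x[0]) if len(x) > 1 else 1.0
    sd0 = max(sd0, step / 2.0)
    # two deterministic starts: weighted moments, and the tallest bin (the
    # moment start can sit on a symmetric saddle for multimodal histograms)
    starts = [(a0, mu0, sd0), (a0, float(x[int(np.argmax(y))]), max(sd0 / 2, step / 2))]
    popt, best_ss = None, np.inf
    for p0 in starts:
        try:
            cand, _ = curve_fit(_gauss, x, y, p0=list(p0), maxfev=10_000)
        except RuntimeError:
            continue
        ss = float(((y - _gauss(x, *cand)) ** 2).sum())
        if ss < best_ss:
            popt, best_ss = cand, ss
    if popt is None:
        raise FitError("Gaussian fit did not converge", init=starts[0])
    a, mu, sd = popt
    resid = y - _gauss(x, *popt)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SpectratypeFit(
        amplitude=float(a), mean=float(mu), sd=abs(float(sd)), r_squared=r2
    )
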