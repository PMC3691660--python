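"""Rarefaction analysis of sequencing completeness.

Increasing random subsets of reads are drawn; each read is traced back to
its contig and each contig to its best-matching reference transcript. The
count of distinct reference transcripts reachable at each subset size gives
a saturation curve, to which the hyperbola

    y(x) = a * x / (b + x)

is fitted: ``a`` is the asymptote (the maximum theoretical number of
reference transcripts discoverable at infinite sequencing depth), ``b`` the
half-saturation read count. observed/a is the sequencing-completeness
ratio, and the analytic slope a*b/(b+x)^2 at the full pool size measures
the remaining discovery rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import AlignmentHit, ReadAssignment

__all__ = [
    "RarefactionDesign",
    "RarefactionPoint",
    "SaturationFit",
    "best_subject_per_contig",
    "rarefy_counts",
    "fit_hyperbolic",
    "saturation_report",
]

log = logging.getLogger("transcensus")

DEFAULT_N_SIZES = 20
DEFAULT_N_REPLICATES = 10


@dataclass(frozen=True)
class RarefactionDesign:
    """Subsampling plan: ``n_sizes`` evenly spaced read counts up to the
    full pool, each drawn ``n_replicates`` times without replacement."""

    n_sizes: int = DEFAULT_N_SIZES
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int = 0

    def sizes(self, pool_size: int) -> list[int]:
        if pool_size < self.n_sizes:
            raise ValueError(
                f"pool of {pool_size} reads cannot support {self.n_sizes} sizes"
            )
        sizes = [round(pool_size * (i + 1) / self.n_sizes) for i in range(self.n_sizes)]
        sizes[-1] = pool_size
        if any(s <= 0 for s in sizes) or any(
            b <= a for a, b in zip(sizes, sizes[1:])
        ):
            raise ValueError("rarefaction sizes must be strictly increasing and > 0")
        return sizes


@dataclass(frozen=True)
class RarefactionPoint:
    size: int
    mean: float
    sd: float


@dataclass
class SaturationFit:
    a: float
    b: float
    points: list[RarefactionPoint]
    slope_at_max: float
    completeness: float
    converged: bool
    residual_ss: float
    diagnostics: str = ""


def hyperbola(x, a, b):
    return a * x / (b + x)


def best_subject_per_contig(hits: Sequence[AlignmentHit]) -> dict[str, str]:
    """One best reference subject per contig from a hit table.

    Ties are broken by bit score (higher wins), then e-value (lower wins),
    then lexicographic subject id — deterministic across input orderings.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        prev = best.get(h.query_id)
        if prev is None:
            best[h.query_id] = h
            continue
        key = (h.bit_score, -h.e_value)
        prev_key = (prev.bit_score, -prev.e_value)
        if key > prev_key or (key == prev_key and h.subject_id < prev.subject_id):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def rarefy_counts(
    assignments: Sequence[ReadAssignment],
    contig_to_ref: Mapping[str, str],
    design: RarefactionDesign,
) -> list[RarefactionPoint]:
    """Distinct-reference counts at each subset size.

    For each size, ``design.n_replicates`` read subsets are drawn without
    replacement; y is the number of distinct reference ids reachable via
    the subset's contigs. Reads without a contig, and contigs without a
    best-hit reference, contribute nothing (they are still drawn — the
    abscissa is raw sequencing effort).
    """
    if not assignments:
        raise ValueError("empty read pool")
    # map each read to an integer reference index (-1 = no reference)
    ref_index: dict[str, int] = {}
    read_ref = np.full(len(assignments), -1, dtype=np.int64)
    for i, a in enumerate(assignments):
        if a.contig_id is None:
            continue
        ref = contig_to_ref.get(a.contig_id)
        if ref is None:
            continue
        read_ref[i] = ref_index.setdefault(ref, len(ref_index))
    n_refs = len(ref_index)
    pool = len(assignments)
    rng = np.random.default_rng(design.seed)
    points: list[RarefactionPoint] = []
    for size in design.sizes(pool):
        ys = np.empty(design.n_replicates)
        for r in range(design.n_replicates):
            idx = rng.choice(pool, size=size, replace=False)
            refs = read_ref[idx]
            refs = refs[refs >= 0]
            if refs.size:
                mask = np.zeros(n_refs, dtype=bool)
                mask[refs] = True
                ys[r] = int(mask.sum())
            else:
                ys[r] = 0
        points.append(
            RarefactionPoint(size=size, mean=float(ys.mean()), sd=float(ys.std(ddof=0)))
        )
    return points


def fit_hyperbolic(
    points: Sequence[RarefactionPoint] | Sequence[tuple[float, float]],
    observed: float | None = None,
    max_restarts: int = 5,
) -> SaturationFit:
    """Fit y = a*x/(b+x) to per-size mean counts by least squares.

    Initialization: a0 = 1.1 * max(y); b0 = the x whose y is closest to
    a0/2; on failure up to ``max_restarts`` jittered restarts. Parameters
    are bounded positive. A flat or non-increasing curve drives b to its
    lower bound; that is flagged as a boundary non-convergence.
    """
    pts = [
        p if isinstance(p, RarefactionPoint) else RarefactionPoint(p[0], p[1], 0.0)
        for p in points
    ]
    if len({p.size for p in pts}) < 3:
        raise ValueError("need at least 3 distinct sample sizes to fit")
    x = np.array([p.size for p in pts], dtype=float)
    y = np.array([p.mean for p in pts], dtype=float)
    if np.any(y < 0):
        raise ValueError("mean counts must be non-negative")

    ymax = float(y.max())
    if ymax == 0:
        return SaturationFit(
            a=0.0, b=0.0, points=pts, slope_at_max=0.0, completeness=0.0,
            converged=False, residual_ss=0.0, diagnostics="all-zero curve",
        )
    a0 = 1.1 * ymax
    b0 = float(x[np.argmin(np.abs(y - a0 / 2))])
    b_floor = 1e-9 * float(x.max())
    bounds = ([1e-12, b_floor], [np.inf, np.inf])

    rng = np.random.default_rng(12345)
    best: tuple[float, float, float] | None = None  # (rss, a, b)
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = (a0, max(b0, b_floor * 10))
        else:
            p0 = (
                a0 * rng.uniform(0.5, 2.0),
                max(b0, b_floor * 10) * rng.uniform(0.2, 5.0),
            )
        try:
            popt, _ = curve_fit(hyperbola, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - hyperbola(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, float(popt[0]), float(popt[1]))

    if best is None:
        return SaturationFit(
            a=float("nan"), b=float("nan"), points=pts, slope_at_max=float("nan"),
            completeness=float("nan"), converged=False,
            residual_ss=float("nan"), diagnostics="optimizer failed on all restarts",
        )
    rss, a, b = best
    x_max = float(x.max())
    slope = a * b / (b + x_max) ** 2
    # b far below the smallest sampled x means the curve is flat over the
    # observed range: the half-saturation constant is unidentifiable
    on_boundary = b <= 1e-3 * float(x.min()) or a <= 1e-10
    y_full = float(y[np.argmax(x)]) if observed is None else float(observed)
    completeness = y_full / a if a > 0 else float("nan")
    return SaturationFit(
        a=a, b=b, points=pts, slope_at_max=slope,
        completeness=completeness,
        converged=not on_boundary,
        residual_ss=rss,
        diagnostics="boundary" if on_boundary else "",
    )


def saturation_report(fit: SaturationFit, observed: int) -> dict:
    """Headline numbers of a saturation analysis.

    The completeness ratio observed/a is the robust quantity: it stays
    nearly constant across different reference sets even though a and the
    observed count individually shift with the reference.
    """
    if not fit.converged:
        raise ValueError(f"fit did not converge ({fit.diagnostics})")
    completeness = observed / fit.a
    return {
        "a": fit.a,
        "b": fit.b,
        "observed": observed,
        "completeness": completeness,
        "completeness_pct": round(100 * completeness),
        "slope_at_max": fit.slope_at_max,
    }
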