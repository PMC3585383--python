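"""Capture-recapture estimation of mammalian lincRNome sizes.

The human and mouse genomes each encode an unknown number of long
intergenic non-coding RNAs (lincRNAs, transcripts > 200 nt outside
annotated genes).  Experimentally validated lincRNA catalogues are
treated as uniform random samples (sizes ``Lh``, ``Lm``) from the
complete, latent lincRNomes (sizes ``Nh``, ``Nm``), which share an
orthologous pool of size ``Nb``.  Observing how often a validated
lincRNA of one species has an expressed ortholog in the other
(``Kh``, ``Km``) and how often both members of an orthologous pair are
independently validated (``Kb``, the "recaptures") identifies all
three pool sizes by maximum likelihood -- a two-species variant of the
classical Lincoln-Petersen mark-recapture estimator.

The module is organised in the order the method runs:

1. estimator -- sampling likelihood, closed-form and numeric ML
   estimates of (Nh, Nm, Nb), curvature-based confidence ellipsoid,
   bootstrap resampling, conservation percentages;
2. pipeline  -- produces the five evidence counts from transcript
   models (BED), sequences (FASTA), per-tissue expression tables and a
   pre-computed cross-species coordinate mapping, applying strand-aware
   merging, one-to-one interval orthology, ORF / indel / expression
   filters;
3. synthetic data -- generates evidence counts from the three-pool
   model and full toy datasets with known ground truth;
4. reporting -- threshold grids and serialization.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, root
from scipy.special import gammaln

__all__ = [
    # errors
    "InvalidCountsError",
    "EstimationUndefinedError",
    "NumericalFailureError",
    # estimator
    "EvidenceCounts",
    "PoolSizes",
    "EstimateReport",
    "ConfidenceEllipsoid",
    "BootstrapResult",
    "log_likelihood",
    "mle_closed_form",
    "mle_numeric",
    "integerize",
    "conservation",
    "analytic_confidence",
    "bootstrap",
    "estimate_report",
    # pipeline
    "GenomicInterval",
    "TranscriptRecord",
    "OrthologPair",
    "ThresholdConfig",
    "read_bed",
    "write_bed",
    "read_fasta",
    "read_expression",
    "read_mapping",
    "read_counts_table",
    "merge_overlapping",
    "intersect_pairs",
    "longest_orf_nt",
    "filter_by_orf",
    "rpkm",
    "max_expression",
    "expression_cutoff",
    "indel_pct",
    "assemble_counts",
    "genome_fraction",
    # synthetic data
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_transcriptome",
    # reporting
    "ThresholdGrid",
    "run_grid",
    "render_report",
]

logger = logging.getLogger("lincnome")

#: minimal same-strand overlap (bp) for an orthologous pair
DEFAULT_MIN_OVERLAP = 100
#: validated lincRNAs must be at least this long (nt)
MIN_LINC_LENGTH = 200
#: ORF length thresholds used for coding-potential filtering (nt)
ORF_THRESHOLDS = (90, 120, 150, None)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class InvalidCountsError(ValueError):
    """Evidence counts violate the model's ordering constraints."""


class EstimationUndefinedError(ValueError):
    """No overlap observed (Kb = 0); pool sizes are unbounded."""


class NumericalFailureError(RuntimeError):
    """A numeric routine failed (e.g. curvature not negative definite)."""


# ---------------------------------------------------------------------------
# estimator: domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceCounts:
    """The five observed counts driving the estimator.

    Lh, Lm : sizes of the validated human / mouse lincRNA sets.
    Kh     : validated human lincRNAs with an expressed ortholog in mouse.
    Km     : the analogous mouse count.
    Kb     : validated human lincRNAs whose mouse ortholog is itself a
             validated mouse lincRNA (the doubly-marked recaptures).
    """

    Lh: int
    Lm: int
    Kh: int
    Km: int
    Kb: int

    def __post_init__(self) -> None:
        for name in ("Lh", "Lm", "Kh", "Km", "Kb"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise InvalidCountsError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise InvalidCountsError(f"{name} must be non-negative, got {v}")
        if not (self.Kb <= self.Kh <= self.Lh):
            raise InvalidCountsError(
                f"need Kb <= Kh <= Lh, got Kb={self.Kb}, Kh={self.Kh}, Lh={self.Lh}"
            )
        if not (self.Kb <= self.Km <= self.Lm):
            raise InvalidCountsError(
                f"need Kb <= Km <= Lm, got Kb={self.Kb}, Km={self.Km}, Lm={self.Lm}"
            )

    def swapped(self) -> "EvidenceCounts":
        """Counts with the two species' roles exchanged."""
        return EvidenceCounts(self.Lm, self.Lh, self.Km, self.Kh, self.Kb)


@dataclass(frozen=True)
class PoolSizes:
    """Latent pool sizes: total lincRNomes Nh, Nm and shared pool Nb."""

    Nh: float
    Nm: float
    Nb: float

    def __post_init__(self) -> None:
        if not (self.Nh > 0 and self.Nm > 0 and self.Nb > 0):
            raise ValueError(f"pool sizes must be strictly positive: {self}")
        if self.Nb > min(self.Nh, self.Nm) + 1e-9:
            raise ValueError(f"need Nb <= min(Nh, Nm): {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.Nh, self.Nm, self.Nb], dtype=float)


@dataclass(frozen=True)
class EstimateReport:
    """Point estimate plus derived conservation percentages."""

    point: PoolSizes
    conservation_human: int
    conservation_mouse: int
    loglik_at_mle: float


@dataclass(frozen=True)
class ConfidenceEllipsoid:
    """Curvature-based confidence region around the ML estimate.

    The log-likelihood surface near its maximum is approximated by the
    quadratic form given by the Hessian ``H``; the confidence region is
    an ellipsoid whose axes are the eigenvectors of ``H`` with
    half-widths ``1/sqrt(-eigenvalue)``.  Per-parameter 95% intervals
    use the Wald convention ``1.96 * sqrt(diag((-H)^-1))``.
    """

    axes_directions: np.ndarray  # (3, 3); column i is axis i
    axes_halfwidths: np.ndarray  # (3,)
    per_parameter_95ci: np.ndarray  # (3,) half-widths for (Nh, Nm, Nb)


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate estimates and percentile intervals from resampling."""

    replicate_estimates: list[PoolSizes]
    ci_95: dict[str, tuple[float, float]]
    seed: int
    n_requested: int
    n_skipped_kb_zero: int


# ---------------------------------------------------------------------------
# estimator: sampling likelihood
# ---------------------------------------------------------------------------


def _log_choose(n: float, k: float) -> float:
    """log C(n, k) via log-gamma; valid for real n >= k >= 0."""
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _feasible(pools: Sequence[float], counts: EvidenceCounts) -> bool:
    nh, nm, nb = pools
    c = counts
    return (
        nb <= min(nh, nm)
        and c.Kh <= nb
        and c.Km - c.Kb <= nb - c.Kh
        and c.Lh - c.Kh <= nh - nb
        and c.Lm - c.Km <= nm - nb
    )


def log_likelihood(pools: PoolSizes | Sequence[float], counts: EvidenceCounts) -> float:
    """Natural-log probability of observing (Kh, Km, Kb).

    ``Lh`` human lincRNAs are drawn uniformly without replacement from
    the ``Nh`` pool (of which ``Nb`` are shared), independently ``Lm``
    from the ``Nm`` pool.  ``Kh`` human draws land in the shared pool,
    ``Km`` mouse draws likewise, and ``Kb`` shared members are drawn by
    both species.  Counting the equally likely sample pairs gives

        P = C(Nb,Kh) C(Nh-Nb, Lh-Kh) / C(Nh, Lh)
            * C(Kh,Kb) C(Nb-Kh, Km-Kb) C(Nm-Nb, Lm-Km) / C(Nm, Lm)

    evaluated with exact log-gamma arithmetic.  Pool sizes incompatible
    with the counts have probability zero and return ``-inf``.
    """
    if isinstance(pools, PoolSizes):
        x = (pools.Nh, pools.Nm, pools.Nb)
    else:
        x = tuple(float(v) for v in pools)
    if not _feasible(x, counts):
        return float("-inf")
    nh, nm, nb = x
    c = counts
    return float(
        _log_choose(nb, c.Kh)
        + _log_choose(nh - nb, c.Lh - c.Kh)
        - _log_choose(nh, c.Lh)
        + _log_choose(c.Kh, c.Kb)
        + _log_choose(nb - c.Kh, c.Km - c.Kb)
        + _log_choose(nm - nb, c.Lm - c.Km)
        - _log_choose(nm, c.Lm)
    )


# ---------------------------------------------------------------------------
# estimator: maximum likelihood
# ---------------------------------------------------------------------------


def mle_closed_form(counts: EvidenceCounts) -> PoolSizes:
    """Closed-form ML estimates (real-valued, before integerization).

        Nh = Lh * Km / Kb,   Nm = Lm * Kh / Kb,   Nb = Kh * Km / Kb

    These solve the score equations obtained from the Stirling
    approximation of the sampling likelihood; see :func:`mle_numeric`.
    """
    c = counts
    if c.Kb < 1:
        raise EstimationUndefinedError("no overlap observed; pool sizes unbounded")
    if c.Kh < 1 or c.Km < 1:
        raise EstimationUndefinedError("Kh and Km must be at least 1")
    return PoolSizes(
        Nh=c.Lh * c.Km / c.Kb,
        Nm=c.Lm * c.Kh / c.Kb,
        Nb=c.Kh * c.Km / c.Kb,
    )


def _slack_to_pools(z: np.ndarray, c: EvidenceCounts) -> np.ndarray:
    """Map unconstrained slack variables to a strictly feasible interior
    point: Nb = (Kh+Km-Kb) + e^a, Nh = Nb + (Lh-Kh) + e^b, etc."""
    a, b, d = z
    nb = c.Kh + c.Km - c.Kb + math.exp(a)
    return np.array(
        [nb + (c.Lh - c.Kh) + math.exp(b), nb + (c.Lm - c.Km) + math.exp(d), nb]
    )


def _stirling_neg_loglik(
    z: np.ndarray, c: EvidenceCounts
) -> tuple[float, np.ndarray]:
    """Negative Stirling-approximated log-likelihood and its gradient.

    Each log-factorial is replaced by its leading Stirling term
    ``n log n - n`` (constant terms in the counts dropped), so the
    stationarity conditions are log-ratio score equations, e.g. for
    Nh:  log(Nh-Nb) - log(Nh-Nb-(Lh-Kh)) - log Nh + log(Nh-Lh) = 0,
    whose solution is the closed form Nh = Lh*Km/Kb.  Evaluated on the
    slack parametrization, where every log argument stays positive and
    the objective grows without bound at infinity (maximization is
    well-posed where root-finding on the score is not: the score also
    vanishes as the pools diverge).
    """
    nh, nm, nb = _slack_to_pools(z, c)

    def lnf(n: float) -> float:  # first-order Stirling log-factorial
        return n * math.log(n) - n if n > 0 else 0.0

    pieces = [
        (1, nb), (-1, nb - c.Kh),
        (1, nh - nb), (-1, nh - nb - (c.Lh - c.Kh)),
        (-1, nh), (1, nh - c.Lh),
        (1, nb - c.Kh), (-1, nb - c.Kh - (c.Km - c.Kb)),
        (1, nm - nb), (-1, nm - nb - (c.Lm - c.Km)),
        (-1, nm), (1, nm - c.Lm),
    ]
    loglik = sum(sign * lnf(v) for sign, v in pieces)

    def lg(v: float) -> float:
        return math.log(v) if v > 0 else 0.0

    dh = lg(nh - nb) - lg(nh - nb - (c.Lh - c.Kh)) - lg(nh) + lg(nh - c.Lh)
    dm = lg(nm - nb) - lg(nm - nb - (c.Lm - c.Km)) - lg(nm) + lg(nm - c.Lm)
    db = (
        lg(nb) - lg(nb - c.Kh - (c.Km - c.Kb))
        - (lg(nh - nb) - lg(nh - nb - (c.Lh - c.Kh)))
        - (lg(nm - nb) - lg(nm - nb - (c.Lm - c.Km)))
    )
    ea, eb, ec = np.exp(z)
    grad = -np.array([ea * (dh + dm + db), eb * dh, ec * dm])
    return -loglik, grad


def _integer_ascent(
    start: np.ndarray, counts: EvidenceCounts, max_iter: int = 100_000
) -> np.ndarray:
    """Greedy ascent of the exact log-likelihood on the integer lattice."""
    cur = np.rint(start).astype(int)
    # nudge into the feasible cone if rounding stepped out
    cur[2] = max(cur[2], counts.Kh + counts.Km - counts.Kb, 1)
    cur[0] = max(cur[0], cur[2] + counts.Lh - counts.Kh, counts.Lh)
    cur[1] = max(cur[1], cur[2] + counts.Lm - counts.Km, counts.Lm)
    best = log_likelihood(cur, counts)
    steps = [
        np.array(d)
        for d in (
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
            (1, 1, 1), (-1, -1, -1), (1, 1, 0), (-1, -1, 0),
            (1, 0, 1), (-1, 0, -1), (0, 1, 1), (0, -1, -1),
        )
    ]
    for _ in range(max_iter):
        improved = False
        for d in steps:
            cand = cur + d
            v = log_likelihood(cand, counts)
            if v > best:
                cur, best = cand, v
                improved = True
        if not improved:
            break
    return cur.astype(float)


def mle_numeric(
    counts: EvidenceCounts,
    search_bounds: tuple[tuple[float, float], ...] | None = None,
    likelihood: str = "stirling",
) -> PoolSizes:
    """Numeric maximum-likelihood estimate of the pool sizes.

    Parameters
    ----------
    counts
        Observed evidence counts; requires ``Kb >= 1``.
    search_bounds
        Optional ``((lo, hi),) * 3`` box for (Nh, Nm, Nb).  A maximizer
        on the box boundary triggers a warning.
    likelihood
        ``"stirling"`` (default) solves the score system obtained from
        the Stirling approximation of the sampling likelihood -- the
        system whose exact solution is the closed form.  ``"exact"``
        performs greedy integer ascent of the exact log-gamma
        log-likelihood instead; at desk scale its argmax sits on a very
        flat ridge a few units away from the closed form.
    """
    c = counts
    if c.Kb < 1:
        raise EstimationUndefinedError("no overlap observed; pool sizes unbounded")
    cf = mle_closed_form(counts)
    on_boundary = (
        c.Kh == c.Lh or c.Km == c.Lm or c.Kb == c.Kh or c.Kb == c.Km
    )
    if likelihood == "exact":
        sol = _integer_ascent(cf.as_array(), counts)
    elif on_boundary:
        # complete-overlap style counts: the Stirling score has log(0)
        # singularities on the feasibility boundary where the supremum
        # sits; the closed form is the boundary solution.
        logger.warning("MLE lies on a feasibility boundary; returning closed form")
        sol = cf.as_array()
    else:
        z0 = np.array(
            [
                math.log(0.5 * (c.Kh + c.Km - c.Kb) + 1.0),
                math.log(float(c.Lh)),
                math.log(float(c.Lm)),
            ]
        )
        res = minimize(
            _stirling_neg_loglik,
            z0,
            args=(counts,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 20_000, "ftol": 1e-17, "gtol": 1e-14},
        )
        # polish: Newton steps on the score from the near-optimal point
        # (root-finding alone diverges -- the score also vanishes at
        # infinity -- but is quadratically convergent this close)
        def score_of(z: np.ndarray) -> np.ndarray:
            # the slack-space gradient is the score scaled by e^z
            return _stirling_neg_loglik(z, counts)[1] / np.exp(z)

        polished = root(score_of, res.x, method="hybr", tol=1e-13)
        z_best = min((res.x, polished.x), key=lambda z: np.max(np.abs(score_of(z))))
        score_norm = float(np.max(np.abs(score_of(z_best))))
        if score_norm > 1e-8:
            raise NumericalFailureError(
                f"likelihood maximization did not reach stationarity "
                f"(|score|={score_norm:.2e})"
            )
        sol = _slack_to_pools(z_best, counts)
    if search_bounds is not None:
        lo = np.array([b[0] for b in search_bounds], dtype=float)
        hi = np.array([b[1] for b in search_bounds], dtype=float)
        clipped = np.clip(sol, lo, hi)
        if not np.allclose(clipped, sol):
            logger.warning("maximizer clipped to search boundary: %s -> %s", sol, clipped)
        sol = clipped
    return PoolSizes(*sol)


def integerize(estimate: PoolSizes) -> PoolSizes:
    """Truncate each real-valued pool size toward zero (floor).

    Matches the printed-table convention in which e.g. 55,999.98 is
    reported as 55,999.
    """
    return PoolSizes(
        Nh=float(math.floor(estimate.Nh)),
        Nm=float(math.floor(estimate.Nm)),
        Nb=float(math.floor(estimate.Nb)),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def conservation(pools: PoolSizes) -> tuple[int, int]:
    """Conserved fraction of each lincRNome, as nearest-integer percents.

    Returns ``(round(100*Nb/Nh), round(100*Nb/Nm))``.
    """
    if pools.Nh <= 0 or pools.Nm <= 0:
        raise ValueError("pool sizes must be positive")
    return (
        _round_half_up(100.0 * pools.Nb / pools.Nh),
        _round_half_up(100.0 * pools.Nb / pools.Nm),
    )


def estimate_report(
    counts: EvidenceCounts, rounding: str = "floor"
) -> EstimateReport:
    """Closed-form estimate packaged with conservation percentages.

    ``rounding`` selects the printed-point convention: ``"floor"``
    (table convention) or ``"nearest"``.
    """
    raw = mle_closed_form(counts)
    if rounding == "floor":
        point = integerize(raw)
    elif rounding == "nearest":
        point = PoolSizes(*(float(_round_half_up(v)) for v in raw.as_array()))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    ch, cm = conservation(raw)  # percentages from the unrounded estimate
    return EstimateReport(
        point=point,
        conservation_human=ch,
        conservation_mouse=cm,
        loglik_at_mle=log_likelihood(raw, counts),
    )


# ---------------------------------------------------------------------------
# estimator: confidence regions
# ---------------------------------------------------------------------------


def _hessian(x: np.ndarray, counts: EvidenceCounts) -> np.ndarray:
    """Central finite-difference Hessian of the exact log-likelihood."""
    h = np.maximum(1e-4 * np.abs(x), 1.0)
    H = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3)
            ej = np.zeros(3)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                log_likelihood(x + ei + ej, counts)
                - log_likelihood(x + ei - ej, counts)
                - log_likelihood(x - ei + ej, counts)
                + log_likelihood(x - ei - ej, counts)
            ) / (4.0 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        raise NumericalFailureError(
            "Hessian stencil crossed the feasibility boundary; MLE not interior"
        )
    return H


def analytic_confidence(
    counts: EvidenceCounts, mle: PoolSizes | None = None
) -> ConfidenceEllipsoid:
    """Confidence ellipsoid from the curvature of log P at the MLE.

    Eigenvectors of the Hessian give the axis directions; axis
    half-widths are the inverse square roots of the negated
    eigenvalues.  Per-parameter 95% half-widths are
    ``1.96 * sqrt(diag((-H)^-1))`` (Wald intervals).
    """
    if counts.Kb < 2:
        raise EstimationUndefinedError("need Kb >= 2 for a confidence region")
    x = (mle if mle is not None else mle_closed_form(counts)).as_array()
    H = _hessian(x, counts)
    eigvals, eigvecs = np.linalg.eigh(H)
    if np.any(eigvals >= 0):
        raise NumericalFailureError(
            f"curvature not negative definite at claimed maximum: {eigvals}"
        )
    halfwidths = 1.0 / np.sqrt(-eigvals)
    cov = np.linalg.inv(-H)
    per_param = 1.96 * np.sqrt(np.diag(cov))
    return ConfidenceEllipsoid(
        axes_directions=eigvecs,
        axes_halfwidths=halfwidths,
        per_parameter_95ci=per_param,
    )


# ---------------------------------------------------------------------------
# estimator: bootstrap
# ---------------------------------------------------------------------------


def bootstrap(
    counts: EvidenceCounts, resamples: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Nonparametric bootstrap of the closed-form estimator.

    Membership labels consistent with the counts are reconstructed:
    ``Kb`` doubly-validated pairs (identity preserved across species),
    ``Kh - Kb`` / ``Km - Kb`` members with an expressed ortholog only,
    and the remainder with no detected ortholog.  Each species' set is
    independently resampled with replacement and reduced to its unique
    members (a resampled catalogue, like a resampled validated set
    after cluster merging, contains each lincRNA at most once); the
    five counts are then recounted from the resampled sets and the
    closed-form estimate recorded.  Replicates with no doubly-validated
    pair (Kb = 0) are skipped and counted.
    """
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    c = counts
    rng = np.random.default_rng(seed)
    # item encoding: ids < Kb are pair members (shared identity across
    # species); ids < Kh (resp. Km) have an expressed ortholog.
    reps: list[PoolSizes] = []
    skipped = 0
    for _ in range(resamples):
        hu = np.unique(rng.integers(0, c.Lh, c.Lh))
        mu = np.unique(rng.integers(0, c.Lm, c.Lm))
        lh, lm = hu.size, mu.size
        kh = int(np.count_nonzero(hu < c.Kh))
        km = int(np.count_nonzero(mu < c.Km))
        kb = int(np.intersect1d(hu[hu < c.Kb], mu[mu < c.Kb]).size)
        if kb == 0:
            skipped += 1
            continue
        reps.append(
            PoolSizes(Nh=lh * km / kb, Nm=lm * kh / kb, Nb=kh * km / kb)
        )
    if not reps:
        raise EstimationUndefinedError("every bootstrap replicate had Kb = 0")
    arr = np.array([p.as_array() for p in reps])
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    ci = {
        name: (float(lo[i]), float(hi[i]))
        for i, name in enumerate(("Nh", "Nm", "Nb"))
    }
    return BootstrapResult(
        replicate_estimates=reps,
        ci_95=ci,
        seed=seed,
        n_requested=resamples,
        n_skipped_kb_zero=skipped,
    )


# ---------------------------------------------------------------------------
# pipeline: domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on a fixed strand (BED convention)."""

    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Bases of same-chromosome, same-strand overlap (0 if none)."""
        if self.chromosome != other.chromosome or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptRecord:
    """A stranded, exon-structured transcript model.

    ``exons`` are non-overlapping, coordinate-sorted intervals on one
    chromosome/strand; ``sequence`` (sense strand) and ``expression``
    are optional attributes attached as the pipeline progresses.
    """

    id: str
    species: str
    exons: list[GenomicInterval]
    sequence: str | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.id}: transcript needs at least one exon")
        chrom = {e.chromosome for e in self.exons}
        strand = {e.strand for e in self.exons}
        if len(chrom) != 1 or len(strand) != 1:
            raise ValueError(f"{self.id}: exons span multiple chromosomes/strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.id}: overlapping exons")

    @property
    def chromosome(self) -> str:
        return self.exons[0].chromosome

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class OrthologPair:
    """A cross-species pairing between a query and its counterpart."""

    query_id: str
    counterpart_id: str
    overlap_bp: int
    indel_pct: float
    counterpart_expression: float | None = None


@dataclass(frozen=True)
class ThresholdConfig:
    """Filter thresholds applied when assembling the evidence counts.

    orf_max_nt
        Transcripts whose longest ORF is >= this many nt are removed
        (the kept set has ORFs strictly below the threshold); ``None``
        disables the filter.
    indel_max_pct
        Ortholog pairs with indel percentage above this are removed
        from the expressed-ortholog counts.
    expression_percentile
        Keep-percentage q: putative ortholog expression must reach the
        (100-q)-th nearest-rank percentile of the validated-pair
        reference expressions; ``None`` disables the cutoff.
    min_overlap_bp
        Minimal same-strand overlap for a validated-validated pair.
    """

    orf_max_nt: int | None = 120
    indel_max_pct: float = 95.0
    expression_percentile: int | None = 95
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        if self.orf_max_nt is not None and self.orf_max_nt <= 0:
            raise ValueError("orf_max_nt must be positive or None")
        if not (0 < self.indel_max_pct <= 100):
            raise ValueError("indel_max_pct must be in (0, 100]")
        if self.expression_percentile is not None and not (
            0 < self.expression_percentile <= 100
        ):
            raise ValueError("expression_percentile must be in (0, 100] or None")


# ---------------------------------------------------------------------------
# pipeline: file formats
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, species: str) -> list[TranscriptRecord]:
    """Read transcript models from BED6 or BED12.

    BED12 block definitions become exons; BED6 records are single-exon.
    """
    records: list[TranscriptRecord] = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: need at least BED6 (got {df.shape[1]} columns)")
    for row in df.itertuples(index=False):
        chrom, start, end, name, _score, strand = row[:6]
        start, end = int(start), int(end)
        if df.shape[1] >= 12:
            sizes = [int(s) for s in str(row[10]).rstrip(",").split(",")]
            starts = [int(s) for s in str(row[11]).rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
        else:
            exons = [GenomicInterval(chrom, start, end, strand)]
        records.append(TranscriptRecord(id=name, species=species, exons=exons))
    return records


def write_bed(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript models as BED12 (exon blocks preserved)."""
    with open(path, "w") as fh:
        for r in records:
            sizes = ",".join(str(len(e)) for e in r.exons) + ","
            starts = ",".join(str(e.start - r.start) for e in r.exons) + ","
            fh.write(
                "\t".join(
                    [
                        r.chromosome,
                        str(r.start),
                        str(r.end),
                        r.id,
                        "0",
                        r.strand,
                        str(r.start),
                        str(r.end),
                        "0",
                        str(len(r.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_expression(
    path: str | Path, library_sizes: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Read a per-tissue expression table (`transcript_id` + tissue columns).

    Values are RPKM unless ``library_sizes`` (mapped reads per tissue)
    is given, in which case the table must also carry a ``length_bp``
    column of exonic lengths and values are raw counts converted here.
    """
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError(f"{path}: missing 'transcript_id' column")
    df = df.set_index("transcript_id")
    if library_sizes is not None:
        if "length_bp" not in df.columns:
            raise ValueError("count tables need a 'length_bp' column")
        lengths = df.pop("length_bp")
        for tissue in df.columns:
            if tissue not in library_sizes:
                raise ValueError(f"no library size for tissue {tissue!r}")
            df[tissue] = [
                rpkm(int(v), int(l), int(library_sizes[tissue]))
                for v, l in zip(df[tissue], lengths)
            ]
    elif "length_bp" in df.columns:
        df = df.drop(columns=["length_bp"])
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read a cross-species coordinate mapping table.

    Columns: ``query_id chrom start end strand [exon_len]`` giving each
    query transcript's location in the counterpart genome (liftOver-style
    output, consumed not computed).  ``exon_len`` is the exonic length
    of the counterpart exon model; 0 or absence marks transcripts whose
    exon model could not be determined.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"query_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: mapping table needs columns {sorted(required)}")
    if "exon_len" not in df.columns:
        df["exon_len"] = (df["end"] - df["start"]).astype(int)
    if df["query_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate query ids in mapping table")
    return df.set_index("query_id")


def read_counts_table(path: str | Path) -> list[tuple[str, EvidenceCounts]]:
    """Read labelled evidence counts from a TSV with header Lh Lm Kh Km Kb.

    An optional first column (any name other than the five counts)
    labels each row; otherwise rows are numbered.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["Lh", "Lm", "Kh", "Km", "Kb"]
    if not set(needed).issubset(df.columns):
        raise ValueError(f"{path}: counts table needs columns {needed}")
    label_cols = [c for c in df.columns if c not in needed]
    out = []
    for i, row in df.iterrows():
        label = str(row[label_cols[0]]) if label_cols else str(i)
        out.append((label, EvidenceCounts(*(int(row[c]) for c in needed))))
    return out


# ---------------------------------------------------------------------------
# pipeline: merging and orthology
# ---------------------------------------------------------------------------


def merge_overlapping(
    records: Sequence[TranscriptRecord],
    force_strand: bool = True,
    cluster_prefix: str | None = None,
) -> list[TranscriptRecord]:
    """Transitively merge records whose genomic spans overlap.

    Merging is per chromosome and, when ``force_strand`` (the default,
    mirroring ``mergeBed -s``), per strand.  Cluster ids are assigned
    in coordinate order as ``<prefix>_N``; the prefix defaults to
    ``<species-initial>lclust`` (e.g. ``mlclust`` for mouse clusters).
    """
    if not records:
        return []
    species = records[0].species
    if cluster_prefix is None:
        cluster_prefix = f"{species[0].lower()}lclust"
    keyed: dict[tuple, list[TranscriptRecord]] = {}
    for r in records:
        key = (r.chromosome, r.strand) if force_strand else (r.chromosome,)
        keyed.setdefault(key, []).append(r)
    clusters: list[tuple[str, int, int, str]] = []
    for key in keyed:
        group = sorted(keyed[key], key=lambda r: (r.start, r.end))
        cur_start, cur_end = group[0].start, group[0].end
        strand = group[0].strand
        chrom = group[0].chromosome
        for r in group[1:]:
            if r.start < cur_end:  # half-open: touching intervals stay apart
                cur_end = max(cur_end, r.end)
            else:
                clusters.append((chrom, cur_start, cur_end, strand))
                cur_start, cur_end = r.start, r.end
        clusters.append((chrom, cur_start, cur_end, strand))
    clusters.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    return [
        TranscriptRecord(
            id=f"{cluster_prefix}_{i + 1}",
            species=species,
            exons=[GenomicInterval(chrom, s, e, strand)],
        )
        for i, (chrom, s, e, strand) in enumerate(clusters)
    ]


def intersect_pairs(
    mapped_queries: Sequence[TranscriptRecord],
    targets: Sequence[TranscriptRecord],
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP,
) -> list[OrthologPair]:
    """One-to-one pairing of mapped queries with target transcripts.

    Queries must already be expressed in the target genome's
    coordinates.  Candidate pairs require same-strand span overlap of
    at least ``min_overlap_bp``; one-to-one pairing keeps the
    largest-overlap match per query and per target, breaking ties by
    coordinate order (then id) for determinism.
    """
    candidates: list[tuple[int, TranscriptRecord, TranscriptRecord]] = []
    by_chrom: dict[tuple[str, str], list[TranscriptRecord]] = {}
    for t in targets:
        by_chrom.setdefault((t.chromosome, t.strand), []).append(t)
    for q in mapped_queries:
        for t in by_chrom.get((q.chromosome, q.strand), []):
            ov = q.span.overlap(t.span)
            if ov >= min_overlap_bp:
                candidates.append((ov, q, t))
    # greedy maximum-overlap matching; deterministic tie-break
    candidates.sort(
        key=lambda c: (-c[0], c[1].chromosome, c[1].start, c[1].id, c[2].start, c[2].id)
    )
    used_q: set[str] = set()
    used_t: set[str] = set()
    pairs: list[OrthologPair] = []
    for ov, q, t in candidates:
        if q.id in used_q or t.id in used_t:
            continue
        used_q.add(q.id)
        used_t.add(t.id)
        pairs.append(
            OrthologPair(
                query_id=q.id,
                counterpart_id=t.id,
                overlap_bp=ov,
                indel_pct=indel_pct(q.exonic_length, t.exonic_length),
            )
        )
    pairs.sort(key=lambda p: p.query_id)
    return pairs


# ---------------------------------------------------------------------------
# pipeline: ORF scanning and filters
# ---------------------------------------------------------------------------


def longest_orf_nt(sequence: str) -> int:
    """Length (nt) of the longest qualifying ORF on the sense strand.

    An ORF is a continuous stretch of codons starting at an ATG codon
    -- or at the beginning of the cDNA in any of the three frames, to
    allow for 5'-truncated cDNAs -- and ending at a stop codon (stop
    included in the length).  A stretch that never reaches a stop does
    not qualify.  Returns 0 when no ORF qualifies.
    """
    seq = sequence.upper()
    n = len(seq)
    best = 0
    # candidate starts: beginning of cDNA in each frame, plus every ATG
    starts = [0, 1, 2] + [i for i in range(n - 2) if seq[i : i + 3] == "ATG"]
    # first in-frame stop at or after each position, per frame
    next_stop = [dict(), dict(), dict()]
    for frame in range(3):
        stop_at = None
        for i in range((n - frame) // 3 * 3 + frame - 3, frame - 3, -3):
            if seq[i : i + 3] in STOP_CODONS:
                stop_at = i
            next_stop[frame][i] = stop_at
    for s in starts:
        if s > n - 3:
            continue
        stop = next_stop[s % 3].get(s)
        if stop is not None:
            best = max(best, stop + 3 - s)
    return best


def filter_by_orf(
    records: Sequence[TranscriptRecord],
    sequences: Mapping[str, str] | None = None,
    orf_max_nt: int | None = 120,
) -> list[TranscriptRecord]:
    """Remove putative mRNAs: records with a longest ORF >= ``orf_max_nt``.

    The kept set has ORFs strictly below the threshold.  ``None``
    disables the filter.  Records without a sequence are retained with
    a warning (conservative: no evidence of coding potential).
    """
    if orf_max_nt is None:
        return list(records)
    kept: list[TranscriptRecord] = []
    missing = 0
    for r in records:
        seq = r.sequence
        if seq is None and sequences is not None:
            seq = sequences.get(r.id)
        if seq is None:
            missing += 1
            kept.append(r)
            continue
        if longest_orf_nt(seq) < orf_max_nt:
            kept.append(r)
    if missing:
        logger.warning("ORF filter: %d records had no sequence and were retained", missing)
    return kept


def rpkm(read_count: int, exonic_length_bp: int, mapped_reads_total: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exonic_length_bp <= 0:
        raise ValueError("exonic length must be positive")
    if mapped_reads_total <= 0:
        raise ValueError("library size must be positive")
    return read_count / (exonic_length_bp / 1000.0) / (mapped_reads_total / 1e6)


def max_expression(
    table: pd.DataFrame, transcript_ids: Iterable[str] | None = None
) -> pd.Series:
    """Per-transcript expression: the maximum RPKM across tissues.

    Transcripts absent from the table are treated as unexpressed (0)
    and logged.
    """
    if table.empty:
        raise ValueError("expression table is empty")
    per_row = table.max(axis=1)
    if transcript_ids is None:
        return per_row
    ids = list(transcript_ids)
    missing = [i for i in ids if i not in per_row.index]
    if missing:
        logger.warning(
            "%d transcripts absent from expression table; treated as unexpressed",
            len(missing),
        )
    return per_row.reindex(ids).fillna(0.0)


def expression_cutoff(reference_values: Sequence[float], percentile_keep: int) -> float:
    """RPKM threshold keeping the top ``percentile_keep`` % of a reference.

    Uses the nearest-rank percentile: the (100-q)-th percentile of the
    sorted reference values, i.e. ``sorted[ceil(p/100 * n) - 1]`` with
    ``p = 100 - q``.  Values strictly below the returned threshold are
    discarded downstream.
    """
    vals = sorted(float(v) for v in reference_values)
    if not vals:
        raise ValueError("reference expression list is empty")
    p = 100 - percentile_keep
    if p <= 0:
        return vals[0]
    rank = math.ceil(p / 100.0 * len(vals))
    return vals[min(rank, len(vals)) - 1]


def indel_pct(len_query: int, len_counterpart: int) -> float:
    """Approximate indel percentage from exonic length difference.

    ``100 * |len_query - len_counterpart| / max(len_query, len_counterpart)``.
    """
    if len_query <= 0 or len_counterpart <= 0:
        raise ValueError("exonic lengths must be positive")
    return 100.0 * abs(len_query - len_counterpart) / max(len_query, len_counterpart)


# ---------------------------------------------------------------------------
# pipeline: evidence-count assembly
# ---------------------------------------------------------------------------


def _attach_sequences(
    records: Sequence[TranscriptRecord], sequences: Mapping[str, str] | None
) -> None:
    if sequences is None:
        return
    for r in records:
        if r.sequence is None and r.id in sequences:
            r.sequence = sequences[r.id]


def _records_to_mapped(
    records: Sequence[TranscriptRecord], mapping: pd.DataFrame
) -> dict[str, TranscriptRecord]:
    """Express each query transcript in the counterpart genome's coordinates."""
    mapped: dict[str, TranscriptRecord] = {}
    for r in records:
        if r.id not in mapping.index:
            continue
        row = mapping.loc[r.id]
        mapped[r.id] = TranscriptRecord(
            id=r.id,
            species=r.species,
            exons=[
                GenomicInterval(
                    str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"])
                )
            ],
        )
    return mapped


def _expressed_ortholog_ids(
    validated: Sequence[TranscriptRecord],
    mapping: pd.DataFrame,
    counterpart_expr: pd.DataFrame,
    config: ThresholdConfig,
    reference_expr: Sequence[float],
    attrition: dict[str, int],
    side: str,
) -> set[str]:
    """Ids of validated transcripts whose mapped counterpart passes the
    expression and indel filters (the Kh / Km membership)."""
    with_map = [r for r in validated if r.id in mapping.index]
    attrition[f"{side}_mapped"] = len(with_map)
    with_exons = [r for r in with_map if int(mapping.loc[r.id, "exon_len"]) > 0]
    attrition[f"{side}_exon_model"] = len(with_exons)
    expr = max_expression(counterpart_expr, [r.id for r in with_exons])
    expressed = [r for r in with_exons if expr[r.id] > 0]
    attrition[f"{side}_expressed"] = len(expressed)
    ok_indel = [
        r
        for r in expressed
        if indel_pct(r.exonic_length, int(mapping.loc[r.id, "exon_len"]))
        <= config.indel_max_pct
    ]
    attrition[f"{side}_indel_ok"] = len(ok_indel)
    if config.expression_percentile is not None and len(reference_expr) > 0:
        thr = expression_cutoff(reference_expr, config.expression_percentile)
        final = [r for r in ok_indel if expr[r.id] >= thr]
    else:
        final = ok_indel
    attrition[f"{side}_expression_cutoff"] = len(final)
    return {r.id for r in final}


def assemble_counts(
    human_validated: Sequence[TranscriptRecord],
    mouse_validated: Sequence[TranscriptRecord],
    mapping: Mapping[str, pd.DataFrame],
    expression_h: pd.DataFrame,
    expression_m: pd.DataFrame,
    config: ThresholdConfig = ThresholdConfig(),
    sequences_h: Mapping[str, str] | None = None,
    sequences_m: Mapping[str, str] | None = None,
) -> tuple[EvidenceCounts, dict[str, int]]:
    """Apply the full filter cascade and emit the five evidence counts.

    Stages, in order:

    1. ORF filter on each validated set (-> Lh, Lm);
    2. counterpart mapping + exon-model resolution + nonzero maximal
       expression + indel and expression-percentile cutoffs (-> Kh, Km);
    3. one-to-one validated-vs-validated interval intersection at
       ``min_overlap_bp`` (-> Kb).

    ``mapping`` maps ``"human_to_mouse"`` / ``"mouse_to_human"`` to
    coordinate tables (see :func:`read_mapping`).  ``expression_h`` is
    expression measured in *human* tissues (covering human validated
    transcripts and mapped mouse queries); ``expression_m`` likewise
    for mouse tissues.  Returns the counts and a per-stage attrition
    log.
    """
    ids = [r.id for r in human_validated] + [r.id for r in mouse_validated]
    if len(ids) != len(set(ids)):
        raise ValueError("transcript id collision across input sets")
    _attach_sequences(human_validated, sequences_h)
    _attach_sequences(mouse_validated, sequences_m)
    attrition: dict[str, int] = {
        "human_input": len(human_validated),
        "mouse_input": len(mouse_validated),
    }
    h_valid = filter_by_orf(human_validated, orf_max_nt=config.orf_max_nt)
    m_valid = filter_by_orf(mouse_validated, orf_max_nt=config.orf_max_nt)
    attrition["human_orf_ok"] = len(h_valid)
    attrition["mouse_orf_ok"] = len(m_valid)
    lh, lm = len(h_valid), len(m_valid)
    if lh == 0 or lm == 0:
        counts = EvidenceCounts(lh, lm, 0, 0, 0)
        return counts, attrition

    map_h2m = mapping["human_to_mouse"]
    map_m2h = mapping["mouse_to_human"]

    # Kb: validated-vs-validated one-to-one intersection in each target
    # genome; pairs are keyed on the human side (one-to-one orthology
    # makes the mouse-side count equal up to mapping asymmetries).
    mapped_h = _records_to_mapped(h_valid, map_h2m)
    pairs = intersect_pairs(
        list(mapped_h.values()), m_valid, min_overlap_bp=config.min_overlap_bp
    )
    kb = len(pairs)
    attrition["validated_pairs"] = kb

    # reference expression for the percentile cutoff: counterpart
    # expression of the validated orthologous pairs, per species
    m_expr_of_pairs = max_expression(expression_m, [p.query_id for p in pairs])
    paired_mouse_ids = [p.counterpart_id for p in pairs]
    h_expr_of_pairs = max_expression(expression_h, paired_mouse_ids)

    kh_ids = _expressed_ortholog_ids(
        h_valid, map_h2m, expression_m, config,
        list(m_expr_of_pairs.values), attrition, "human",
    )
    km_ids = _expressed_ortholog_ids(
        m_valid, map_m2h, expression_h, config,
        list(h_expr_of_pairs.values), attrition, "mouse",
    )
    counts = EvidenceCounts(Lh=lh, Lm=lm, Kh=len(kh_ids), Km=len(km_ids), Kb=kb)
    logger.info("assembled evidence counts %s; attrition %s", counts, attrition)
    return counts, attrition


def genome_fraction(
    validated_total_len: float,
    validated_count: int,
    estimated_count: int,
    genome_size: float | None = None,
) -> tuple[float, float | None]:
    """Extrapolate the validated set's total length to the lincRNome.

    ``estimated_total_len = validated_total_len * estimated_count /
    validated_count``; the genome percentage is reported when
    ``genome_size`` is given (same units).
    """
    if validated_count <= 0:
        raise ValueError("validated_count must be positive")
    est_len = validated_total_len * estimated_count / validated_count
    pct = 100.0 * est_len / genome_size if genome_size else None
    return est_len, pct


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the three-pool model and toy datasets.

    Defaults mirror the study conditions: pools of 50,000 / 40,000
    lincRNAs sharing 30,000 orthologs, validated samples of 3,600
    human and 3,300 mouse lincRNAs, 16 human and 10 mouse tissues.
    ``ortholog_detection_prob`` is the chance that a shared member's
    counterpart shows nonzero expression in the other species'
    RNAseq data; 1.0 is the idealized default (the study does not
    quantify it).  Expression is log-normal on the RPKM scale;
    ``orf_fraction`` of transcripts carry a planted ORF with length
    drawn uniformly from ``orf_length_range`` (codon-rounded);
    counterpart exon-model lengths are shrunk by an indel fraction
    drawn uniformly from ``indel_noise_range`` (percent).
    """

    true_pools: PoolSizes = PoolSizes(50_000, 40_000, 30_000)
    sample_sizes: tuple[int, int] = (3_600, 3_300)
    ortholog_detection_prob: float = 1.0
    expression_mu: float = 0.0
    expression_sigma: float = 1.5
    orf_fraction: float = 0.4
    orf_length_range: tuple[int, int] = (60, 300)
    indel_noise_range: tuple[float, float] = (0.0, 50.0)
    tissues: tuple[int, int] = (16, 10)
    seed: int = 0
    correlated_sampling: float = 0.0

    def __post_init__(self) -> None:
        lh, lm = self.sample_sizes
        if lh > self.true_pools.Nh or lm > self.true_pools.Nm:
            raise ValueError("sample sizes cannot exceed pool sizes")
        if lh < 1 or lm < 1:
            raise ValueError("sample sizes must be positive")
        if not (0.0 <= self.ortholog_detection_prob <= 1.0):
            raise ValueError("ortholog_detection_prob must be in [0, 1]")
        if not (0.0 <= self.orf_fraction <= 1.0):
            raise ValueError("orf_fraction must be in [0, 1]")
        if not (0.0 <= self.correlated_sampling <= 1.0):
            raise ValueError("correlated_sampling must be in [0, 1]")


@dataclass
class GroundTruth:
    """True memberships and planted attributes of a simulated dataset.

    Shared-pool members have ids ``s<j>``; species-specific members
    ``h<j>`` / ``m<j>``.  For transcriptome fixtures the per-transcript
    tables record everything a bookkeeping check needs: planted ORF
    length, counterpart exon-model length (after indel noise) and the
    counterpart's maximal expression.
    """

    config: SimulationConfig
    human_sample: list[str]
    mouse_sample: list[str]
    detect_in_mouse: dict[str, bool]  # shared id -> counterpart expressed in mouse
    detect_in_human: dict[str, bool]
    counts: EvidenceCounts
    orf_length: dict[str, int] = field(default_factory=dict)
    counterpart_exon_len: dict[str, int] = field(default_factory=dict)
    counterpart_expression: dict[str, float] = field(default_factory=dict)
    exonic_length: dict[str, int] = field(default_factory=dict)


def _shared_id(j: int) -> str:
    return f"s{j}"


def simulate_counts(config: SimulationConfig) -> tuple[EvidenceCounts, GroundTruth]:
    """Draw evidence counts from the three-pool generative model.

    ``Lh`` ids are sampled uniformly without replacement from the
    ``Nh`` human pool (shared members first), independently ``Lm`` from
    the mouse pool.  A shared member's counterpart is detected
    (nonzero expression) with probability
    ``ortholog_detection_prob``, independently per species.  Kh counts
    sampled human shared members with a detected mouse counterpart; Km
    likewise; Kb counts shared members sampled by both species and
    detected on both sides.

    ``correlated_sampling`` > 0 probes the independence assumption: that
    fraction of the mouse sample's shared slots is forced to reuse
    shared members already in the human sample.
    """
    rng = np.random.default_rng(config.seed)
    nh, nm, nb = (int(v) for v in config.true_pools.as_array())
    lh, lm = config.sample_sizes
    p = config.ortholog_detection_prob

    human_pool = nh  # ids 0..nb-1 shared, nb..nh-1 human-only
    sh = rng.choice(human_pool, size=lh, replace=False)
    sm = rng.choice(nm, size=lm, replace=False)
    if config.correlated_sampling > 0:
        sh_shared = sh[sh < nb]
        sm_list = list(sm)
        sm_shared_idx = [i for i, v in enumerate(sm_list) if v < nb]
        n_force = int(round(config.correlated_sampling * len(sm_shared_idx)))
        reuse = rng.choice(sh_shared, size=min(n_force, sh_shared.size), replace=False)
        taken = set(sm_list)
        for i, v in zip(sm_shared_idx, reuse):
            if v not in taken or sm_list[i] == v:
                taken.discard(sm_list[i])
                sm_list[i] = int(v)
                taken.add(int(v))
        sm = np.array(sm_list)

    det_m = rng.random(nb) < p  # counterpart of shared j expressed in mouse
    det_h = rng.random(nb) < p

    sh_shared = sh[sh < nb]
    sm_shared = sm[sm < nb]
    kh = int(np.count_nonzero(det_m[sh_shared]))
    km = int(np.count_nonzero(det_h[sm_shared]))
    both = np.intersect1d(sh_shared, sm_shared)
    kb = int(np.count_nonzero(det_m[both] & det_h[both]))
    counts = EvidenceCounts(Lh=lh, Lm=lm, Kh=kh, Km=km, Kb=kb)

    def hid(v: int) -> str:
        return _shared_id(v) if v < nb else f"h{v}"

    def mid(v: int) -> str:
        return _shared_id(v) if v < nb else f"m{v}"

    truth = GroundTruth(
        config=config,
        human_sample=[hid(int(v)) for v in np.sort(sh)],
        mouse_sample=[mid(int(v)) for v in np.sort(sm)],
        detect_in_mouse={_shared_id(int(j)): bool(det_m[j]) for j in np.sort(sh_shared)},
        detect_in_human={_shared_id(int(j)): bool(det_h[j]) for j in np.sort(sm_shared)},
        counts=counts,
    )
    return counts, truth


# sequence construction: the background tile is stop-rich in every
# frame and contains no ATG, so the longest qualifying ORF of a
# generated sequence is exactly the planted one (or <= 12 nt of
# cDNA-start read-through when nothing is planted).
_BACKGROUND_TILE = "TTAG"
_SAFE_CODONS = ("GAC", "GAG", "CTC", "CCT", "GGC", "TCC")  # no stops/ATG, none across junctions


def _synthetic_sequence(length: int, orf_len: int, rng: np.random.Generator) -> str:
    """Background tiling with an optional planted ORF of ``orf_len`` nt."""
    tile = (_BACKGROUND_TILE * (length // len(_BACKGROUND_TILE) + 1))[:length]
    if orf_len <= 0:
        return tile
    orf_len = max(9, orf_len // 3 * 3)
    if orf_len + 24 > length:
        orf_len = (length - 24) // 3 * 3
    n_mid = orf_len // 3 - 2
    mid = "".join(rng.choice(_SAFE_CODONS) for _ in range(n_mid))
    orf = "ATG" + mid + "TAA"
    offset = int(rng.integers(12, length - len(orf) - 8))
    return tile[:offset] + orf + tile[offset + len(orf):]


def _slot_interval(
    prefix: str, slot: int, length: int, strand: str
) -> GenomicInterval:
    """Deterministic non-overlapping genomic slot (one chromosome per 1,000)."""
    chrom = f"{prefix}chr{slot // 1000 + 1}"
    start = (slot % 1000) * 5000 + 100
    return GenomicInterval(chrom, start, start + length, strand)


def _format_expr(v: float) -> str:
    return f"{v:.6g}"


def simulate_transcriptome(
    config: SimulationConfig, output_dir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a complete toy dataset (BED/FASTA/expression/mapping).

    Pool member ``j`` (< Nb means shared) becomes transcript
    ``hlinc<j>`` in human and/or ``mlinc<j>`` in mouse; shared members
    occupy the same slot index in both genomes, so doubly-validated
    pairs overlap by at least ``min(len_h, len_m) >= 200`` bp on the
    same strand.  The mapped genomic span of a query always covers the
    counterpart slot; indel noise perturbs only the counterpart
    exon-model length (the ``exon_len`` mapping column), which is what
    the indel filter consumes.  A shared member's counterpart is
    expressed when its Bernoulli detection succeeded *or* the
    counterpart is itself a validated (hence expressed) lincRNA.

    Running :func:`assemble_counts` on the files reproduces the
    bookkeeping derivable from the returned :class:`GroundTruth`
    (planted ORF lengths, exon-model lengths, counterpart
    expressions).  Byte-identical output under identical config+seed.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, truth = simulate_counts(config)
    rng = np.random.default_rng((config.seed, 97))
    nh, nm, nb = (int(v) for v in config.true_pools.as_array())
    th, tm = config.tissues

    # pool ids: "s<j>" has pool id j < nb; "h<v>" / "m<v>" have id v >= nb
    sh = sorted(int(s[1:]) for s in truth.human_sample)
    sm = sorted(int(s[1:]) for s in truth.mouse_sample)
    sh_set, sm_set = set(sh), set(sm)

    # per-member attributes (drawn in fixed order for determinism)
    len_h = np.clip(
        np.rint(rng.lognormal(math.log(800), 0.5, nh)), MIN_LINC_LENGTH, 3000
    ).astype(int)
    len_m_own = np.clip(
        np.rint(rng.lognormal(math.log(800), 0.5, nm)), MIN_LINC_LENGTH, 3000
    ).astype(int)
    lo, hi = config.indel_noise_range
    indel_r = rng.uniform(lo / 100.0, hi / 100.0, nb)
    strand_h = np.where(rng.random(nh) < 0.5, "+", "-")
    strand_m = np.where(rng.random(nm) < 0.5, "+", "-")
    strand_m[:nb] = strand_h[:nb]  # shared loci keep their strand

    # mouse-side exon-model length of shared members: human length
    # shrunk by the indel fraction (floor 30 bp); validated mouse
    # transcripts are still at least 200 nt
    len_m = len_m_own.copy()
    for j in range(nb):
        derived = max(30, int(round(len_h[j] * (1.0 - indel_r[j]))))
        len_m[j] = max(MIN_LINC_LENGTH, derived) if j in sm_set else derived

    def build_records(
        ids: list[int], species: str
    ) -> list[TranscriptRecord]:
        prefix = "h" if species == "human" else "m"
        lengths = len_h if species == "human" else len_m
        strands = strand_h if species == "human" else strand_m
        recs = []
        for j in ids:
            recs.append(
                TranscriptRecord(
                    id=f"{prefix}linc{j}",
                    species=species,
                    exons=[
                        _slot_interval(prefix, j, int(lengths[j]), str(strands[j]))
                    ],
                )
            )
        return recs

    human_records = build_records(sh, "human")
    mouse_records = build_records(sm, "mouse")

    # planted ORFs
    olo, ohi = config.orf_length_range
    for r in human_records + mouse_records:
        planted = 0
        if rng.random() < config.orf_fraction:
            planted = int(rng.integers(olo, ohi + 1)) // 3 * 3
            planted = min(planted, (r.exonic_length - 24) // 3 * 3)
        r.sequence = _synthetic_sequence(r.exonic_length, planted, rng)
        truth.orf_length[r.id] = planted
        truth.exonic_length[r.id] = r.exonic_length

    # detection state including "counterpart itself validated"
    det_m_eff = {
        j: truth.detect_in_mouse.get(_shared_id(j), False) or j in sm_set
        for j in sh if j < nb
    }
    det_h_eff = {
        j: truth.detect_in_human.get(_shared_id(j), False) or j in sh_set
        for j in sm if j < nb
    }

    def expr_row(n_tissues: int, expressed: bool) -> np.ndarray:
        vals = rng.lognormal(config.expression_mu, config.expression_sigma, n_tissues)
        return vals if expressed else np.zeros(n_tissues)

    # expression measured in HUMAN tissues: own rows for validated human
    # lincRNAs plus counterpart rows for mapped mouse queries
    h_tissue_names = [f"tissue{t + 1}" for t in range(th)]
    m_tissue_names = [f"tissue{t + 1}" for t in range(tm)]
    expr_h_rows: dict[str, np.ndarray] = {}
    for j in sh:
        expr_h_rows[f"hlinc{j}"] = expr_row(th, True)
    for j in sm:
        if j < nb:
            row = expr_row(th, det_h_eff[j])
            expr_h_rows[f"mlinc{j}"] = row
            truth.counterpart_expression[f"mlinc{j}"] = float(row.max())
    expr_m_rows: dict[str, np.ndarray] = {}
    for j in sm:
        expr_m_rows[f"mlinc{j}"] = expr_row(tm, True)
    for j in sh:
        if j < nb:
            row = expr_row(tm, det_m_eff[j])
            expr_m_rows[f"hlinc{j}"] = row
            truth.counterpart_expression[f"hlinc{j}"] = float(row.max())

    # mapping tables: shared members map onto the counterpart slot
    map_h2m_rows = []
    for j in sh:
        if j < nb:
            iv = _slot_interval("m", j, int(len_h[j]), str(strand_m[j]))
            map_h2m_rows.append(
                (f"hlinc{j}", iv.chromosome, iv.start, iv.end, iv.strand, int(len_m[j]))
            )
            truth.counterpart_exon_len[f"hlinc{j}"] = int(len_m[j])
    map_m2h_rows = []
    for j in sm:
        if j < nb:
            iv = _slot_interval("h", j, int(len_m[j]), str(strand_h[j]))
            map_m2h_rows.append(
                (f"mlinc{j}", iv.chromosome, iv.start, iv.end, iv.strand, int(len_h[j]))
            )
            truth.counterpart_exon_len[f"mlinc{j}"] = int(len_h[j])

    paths = {
        "human_bed": out / "human.bed",
        "mouse_bed": out / "mouse.bed",
        "human_fasta": out / "human.fa",
        "mouse_fasta": out / "mouse.fa",
        "expression_human": out / "expression_human.tsv",
        "expression_mouse": out / "expression_mouse.tsv",
        "map_human_to_mouse": out / "map_human_to_mouse.tsv",
        "map_mouse_to_human": out / "map_mouse_to_human.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_bed(human_records, paths["human_bed"])
    write_bed(mouse_records, paths["mouse_bed"])
    for key, recs in (("human_fasta", human_records), ("mouse_fasta", mouse_records)):
        with open(paths[key], "w") as fh:
            for r in recs:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.sequence), 60):
                    fh.write(r.sequence[i : i + 60] + "\n")
    for key, rows, names in (
        ("expression_human", expr_h_rows, h_tissue_names),
        ("expression_mouse", expr_m_rows, m_tissue_names),
    ):
        with open(paths[key], "w") as fh:
            fh.write("transcript_id\t" + "\t".join(names) + "\n")
            for tid in sorted(rows):
                fh.write(tid + "\t" + "\t".join(_format_expr(v) for v in rows[tid]) + "\n")
    for key, rows in (
        ("map_human_to_mouse", map_h2m_rows),
        ("map_mouse_to_human", map_m2h_rows),
    ):
        with open(paths[key], "w") as fh:
            fh.write("query_id\tchrom\tstart\tend\tstrand\texon_len\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
    manifest = {
        "counts_model": vars(counts)
        if not isinstance(counts, EvidenceCounts)
        else {k: getattr(counts, k) for k in ("Lh", "Lm", "Kh", "Km", "Kb")},
        "human_sample": truth.human_sample,
        "mouse_sample": truth.mouse_sample,
        "orf_length": truth.orf_length,
        "exonic_length": truth.exonic_length,
        "counterpart_exon_len": truth.counterpart_exon_len,
        "counterpart_expression": truth.counterpart_expression,
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths, truth


# ---------------------------------------------------------------------------
# reporting: threshold grids and serialization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridCell:
    """One threshold combination with its counts and (maybe) estimate."""

    label: str
    orf_max_nt: int | None
    expression_percentile: int | None
    counts: EvidenceCounts
    report: EstimateReport | None  # None when Kb = 0 (undefined cell)


@dataclass(frozen=True)
class ThresholdGrid:
    """Estimates across ORF-threshold / expression-percentile cells."""

    cells: list[GridCell]


def run_grid(
    precomputed_counts: Sequence[tuple[str, EvidenceCounts]] | None = None,
    pipeline_inputs: Mapping[str, object] | None = None,
    orf_thresholds: Sequence[int | None] = ORF_THRESHOLDS,
    expression_percentiles: Sequence[int | None] = (95,),
    rounding: str = "floor",
) -> ThresholdGrid:
    """Compute an estimate per threshold cell.

    Either ``precomputed_counts`` supplies one labelled
    :class:`EvidenceCounts` per cell (e.g. the printed table columns),
    or ``pipeline_inputs`` supplies :func:`assemble_counts` keyword
    arguments (minus the config) and counts are assembled per
    (orf_threshold, expression_percentile) combination.  Cells whose
    counts make the estimate undefined (Kb = 0) are kept with
    ``report=None``.
    """
    cells: list[GridCell] = []

    def make_cell(
        label: str,
        counts: EvidenceCounts,
        orf: int | None,
        q: int | None,
    ) -> GridCell:
        try:
            rep = estimate_report(counts, rounding=rounding)
        except EstimationUndefinedError:
            logger.warning("grid cell %s undefined (Kb = 0)", label)
            rep = None
        return GridCell(label, orf, q, counts, rep)

    if precomputed_counts is not None:
        for label, counts in precomputed_counts:
            cells.append(make_cell(label, counts, None, None))
    elif pipeline_inputs is not None:
        for orf in orf_thresholds:
            for q in expression_percentiles:
                config = ThresholdConfig(
                    orf_max_nt=orf, expression_percentile=q
                )
                counts, _ = assemble_counts(config=config, **pipeline_inputs)
                label = f"orf<{orf if orf is not None else 'none'},exp{q}"
                cells.append(make_cell(label, counts, orf, q))
    else:
        raise ValueError("need precomputed_counts or pipeline_inputs")
    return ThresholdGrid(cells=cells)


def _report_dict(cell: GridCell) -> dict:
    d: dict = {
        "label": cell.label,
        "orf_max_nt": cell.orf_max_nt,
        "expression_percentile": cell.expression_percentile,
        "counts": {k: getattr(cell.counts, k) for k in ("Lh", "Lm", "Kh", "Km", "Kb")},
    }
    if cell.report is None:
        d["point"] = None
    else:
        r = cell.report
        d["point"] = {
            "Nh": int(r.point.Nh),
            "Nm": int(r.point.Nm),
            "Nb": int(r.point.Nb),
        }
        d["conservation"] = {
            "human": r.conservation_human,
            "mouse": r.conservation_mouse,
        }
        d["loglik"] = r.loglik_at_mle
    return d


_TSV_COLUMNS = [
    "label", "Lh", "Lm", "Kh", "Km", "Kb",
    "Nh", "Nm", "Nb", "conservation_human", "conservation_mouse",
]


def render_report(
    grid: ThresholdGrid | GridCell, fmt: str = "tsv"
) -> str:
    """Serialize a grid (or single cell) as ``tsv``, ``json`` or ``text``.

    JSON round-trips losslessly through :func:`json.loads`; undefined
    cells render a sentinel (``NA``) rather than a number.
    """
    cells = grid.cells if isinstance(grid, ThresholdGrid) else [grid]
    if fmt == "json":
        return json.dumps([_report_dict(c) for c in cells], indent=1, sort_keys=True)
    rows = []
    for c in cells:
        row = [c.label] + [getattr(c.counts, k) for k in ("Lh", "Lm", "Kh", "Km", "Kb")]
        if c.report is None:
            row += ["NA"] * 5
        else:
            r = c.report
            row += [
                int(r.point.Nh), int(r.point.Nm), int(r.point.Nb),
                r.conservation_human, r.conservation_mouse,
            ]
        rows.append([str(v) for v in row])
    if fmt == "tsv":
        buf = io.StringIO()
        buf.write("\t".join(_TSV_COLUMNS) + "\n")
        for row in rows:
            buf.write("\t".join(row) + "\n")
        return buf.getvalue()
    if fmt == "text":
        widths = [
            max(len(_TSV_COLUMNS[i]), *(len(r[i]) for r in rows)) if rows else len(_TSV_COLUMNS[i])
            for i in range(len(_TSV_COLUMNS))
        ]
        lines = ["  ".join(h.rjust(w) for h, w in zip(_TSV_COLUMNS, widths))]
        for row in rows:
            lines.append("  ".join(v.rjust(w) for v, w in zip(row, widths)))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")
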