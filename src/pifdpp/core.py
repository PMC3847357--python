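"""Deaths prevented or postponed (DPP) under treatment-uptake changes.

Health-impact models such as IMPACT estimate how many deaths an increase in
the uptake of one or more treatments would prevent or postpone in a diseased
population.  The classic calculation needs the case fatality rate under *no*
treatment, ``cf`` -- a quantity that is rarely observable once the treatments
are already in use, so the observed (treated) fatality rate is substituted
and the benefit is underestimated.  The alternative implemented here uses the
potential impact fraction (PIF): the proportional reduction in the marginal
risk of death when the joint distribution of treatment receipt shifts from a
baseline to a counterfactual target.  The PIF route needs only the observed
baseline death count ``d``, never ``cf``.

Model.  Receipt of the k treatments is a random binary vector
``T = (T_1, ..., T_k)`` following a multivariate Bernoulli distribution; the
uptake ``u_i = P(T_i = 1)`` is its i-th marginal mean.  Risk of death within
the study period is multiplicative with no interaction (the Mant-Hicks
model)::

    R(t_1, ..., t_k) = R_0 * RR_1**t_1 * ... * RR_k**t_k,

with ``R_0 = cf`` and per-treatment relative risks ``RR_i`` (relative risk
reduction ``RRR_i = 1 - RR_i``).  The population-average ("marginal") risk is
then ``cf * PGF_T(RR_1, ..., RR_k)``, where ``PGF_T`` is the probability
generating function of ``T``, so for an uptake shift from ``T`` to ``T*``::

    PIF  = [PGF_T(RR) - PGF_T*(RR)] / PGF_T(RR)
    dDPP = PIF * d                     (per stratum; totals sum over strata)

while the classic route computes ``dDPP = cf * N * [PGF_T(RR) - PGF_T*(RR)]``.
With the true ``cf`` the two coincide; with the observed biased rate
``cf~ = cf * PGF_T(RR)`` the classic route undershoots.

The module is organised in the order a scenario is evaluated:

1. configuration and numeric helpers
2. treatment effects (relative risks)
3. uptake distributions (multivariate Bernoulli: table, independent, moments)
4. classic case-fatality-rate DPP calculations and their bias
5. potential impact fraction engine
6. individual-level cohort simulation (Monte-Carlo validation)
7. scenario files, runner and reports
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PROB_TOL",
    "MAX_TABLE_K",
    "HarmfulTreatmentWarning",
    "round_half_up",
    "TreatmentEffect",
    "UptakeDistribution",
    "from_independent",
    "from_joint_table",
    "joint_moments",
    "moments_to_table",
    "pgf",
    "dpp_single_from_zero",
    "delta_dpp_single",
    "marginal_risk",
    "dpp_combination",
    "delta_dpp_combination",
    "biased_cf",
    "biased_cf_multi",
    "underestimation_factor",
    "CategoricalExposure",
    "pif_categorical",
    "pif_single",
    "pif_independent",
    "pif_general",
    "delta_dpp_from_pif",
    "Stratum",
    "StratumImpact",
    "stratified_delta_dpp",
    "mortality_reduction",
    "percent_difference",
    "SimulatedCohort",
    "simulate_cohort",
    "empirical_pif",
    "random_scenario",
    "Scenario",
    "ResultRow",
    "ImpactResult",
    "load_scenario",
    "example_scenario",
    "run_scenario",
    "render_report",
]

# --------------------------------------------------------------------------
# 1. Configuration and numeric helpers
# --------------------------------------------------------------------------

logger = logging.getLogger("pifdpp")

#: Absolute tolerance for probability normalisation and round-trip checks.
#: Scenario parameters are treated as exact, so this only absorbs float noise.
PROB_TOL = 1e-9

#: Largest k for which the dense 2**k outcome table is materialised.  Beyond
#: this only the independent (factorised) form is accepted.
MAX_TABLE_K = 16


class HarmfulTreatmentWarning(UserWarning):
    """A treatment with relative risk above 1 (harmful); computation proceeds."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    The value is first quantised at 1e-12 so that binary representation noise
    (e.g. 28.96499999999999 for the decimal 28.965) does not flip a tie.
    """
    q = Decimal(repr(float(x))).quantize(Decimal("1e-12"), rounding=ROUND_HALF_UP)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


# --------------------------------------------------------------------------
# 2. Treatment effects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentEffect:
    """A treatment's effect on mortality as a relative risk.

    Parameters
    ----------
    id
        Label used in reports and scenario files.
    rr
        Relative risk ``R_1 / R_0`` of death with vs without the treatment.
        ``rr < 1`` is protective; ``rr = 0`` eliminates risk; ``rr > 1``
        (harmful) is allowed but flagged with :class:`HarmfulTreatmentWarning`
        because the multiplicative relative-benefit formula then leaves [0, 1].
    """

    id: str
    rr: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rr) or self.rr < 0:
            raise ValueError(f"treatment {self.id!r}: rr must be >= 0, got {self.rr!r}")
        if self.rr > 1:
            warnings.warn(
                f"treatment {self.id!r} has rr={self.rr} > 1 (harmful); "
                "DPP and PIF values remain defined but may be negative",
                HarmfulTreatmentWarning,
                stacklevel=3,
            )

    @property
    def rrr(self) -> float:
        """Relative risk reduction, ``1 - rr``."""
        return 1.0 - self.rr

    @classmethod
    def from_rrr(cls, id: str, rrr: float) -> "TreatmentEffect":
        """Construct from a relative risk reduction (``rr = 1 - rrr``)."""
        return cls(id=id, rr=1.0 - float(rrr))


def _as_effects(treatments: Sequence[TreatmentEffect | float]) -> tuple[TreatmentEffect, ...]:
    """Accept TreatmentEffect objects or bare relative risks."""
    out = []
    for i, t in enumerate(treatments):
        if isinstance(t, TreatmentEffect):
            out.append(t)
        else:
            out.append(TreatmentEffect(id=f"t{i + 1}", rr=float(t)))
    return tuple(out)


def _rr_vector(treatments: Sequence[TreatmentEffect | float]) -> np.ndarray:
    return np.array([t.rr for t in _as_effects(treatments)], dtype=float)


# --------------------------------------------------------------------------
# 3. Uptake distributions (multivariate Bernoulli)
# --------------------------------------------------------------------------
#
# Outcome ordering convention: the 2**k joint outcomes are indexed by the
# integer mask whose bit (i-1) is the indicator of treatment i, so treatment 1
# is the least-significant bit.  Bit-string keys in scenario files read left
# to right as treatments 1..k ("10" = treatment 1 present, treatment 2 absent).


def _subset_key(subset: Iterable[int] | str, k: int) -> tuple[int, ...]:
    """Normalise a subset spec ('1,3', (3, 1), ...) to a sorted 1-based tuple."""
    if isinstance(subset, str):
        parts = [p for p in subset.replace(" ", "").split(",") if p]
        idx = tuple(int(p) for p in parts)
    elif isinstance(subset, int):
        idx = (subset,)
    else:
        idx = tuple(int(i) for i in subset)
    idx = tuple(sorted(set(idx)))
    if not idx:
        raise ValueError("moment subsets must be non-empty")
    if idx[0] < 1 or idx[-1] > k:
        raise ValueError(f"subset {idx} out of range for k={k} treatments")
    return idx


def _mask_of(subset: tuple[int, ...]) -> int:
    m = 0
    for i in subset:
        m |= 1 << (i - 1)
    return m


def _bitstring(mask: int, k: int) -> str:
    return "".join(str((mask >> i) & 1) for i in range(k))


def _table_key_to_mask(key: Any, k: int | None = None) -> tuple[int, int]:
    """Parse a joint-table key (bit-string or 0/1 tuple) to (mask, k)."""
    if isinstance(key, str):
        bits = [int(c) for c in key.strip()]
    else:
        bits = [int(b) for b in key]
    if any(b not in (0, 1) for b in bits):
        raise ValueError(f"joint table key {key!r} is not a binary vector")
    if k is not None and len(bits) != k:
        raise ValueError(f"joint table key {key!r} has length {len(bits)}, expected {k}")
    mask = sum(b << i for i, b in enumerate(bits))
    return mask, len(bits)


class UptakeDistribution:
    """Joint law of k binary treatment indicators (multivariate Bernoulli).

    Constructed via :meth:`independent`, :meth:`from_joint_table` or
    :meth:`from_moments`.  Whatever the construction route, the dense outcome
    table is stored (for k <= MAX_TABLE_K) so that moments and the PGF can be
    evaluated by any path; above the cap only the independent factorised form
    is representable.
    """

    def __init__(
        self,
        k: int,
        form: str,
        probs: np.ndarray | None,
        marginals: np.ndarray,
    ) -> None:
        self.k = int(k)
        self.form = form
        self.probs = probs  # length 2**k, or None (independent beyond cap)
        self.marginals = np.asarray(marginals, dtype=float)

    # -- constructors -------------------------------------------------------

    @classmethod
    def independent(
        cls, marginals: Sequence[float], *, max_table_k: int = MAX_TABLE_K
    ) -> "UptakeDistribution":
        """Product law with the given marginal uptakes: p(t) = prod u_i^t_i (1-u_i)^(1-t_i)."""
        u = np.atleast_1d(np.asarray(marginals, dtype=float))
        if u.ndim != 1 or u.size < 1:
            raise ValueError("marginals must be a non-empty 1-D vector")
        bad = np.flatnonzero((u < 0) | (u > 1) | ~np.isfinite(u))
        if bad.size:
            raise ValueError(
                f"marginal uptake for treatment {bad[0] + 1} is {u[bad[0]]!r}, outside [0, 1]"
            )
        k = u.size
        probs = None
        if k <= max_table_k:
            probs = np.array([1.0])
            for ui in u:  # treatment i lands on bit i-1: kron puts it on the high bit
                probs = np.kron(np.array([1.0 - ui, ui]), probs)
        return cls(k=k, form="independent", probs=probs, marginals=u)

    @classmethod
    def from_joint_table(
        cls, table: Mapping[Any, float] | Sequence[float] | np.ndarray
    ) -> "UptakeDistribution":
        """Validate and store an explicit 2**k outcome table.

        ``table`` is either a mapping from binary vectors (bit-strings or 0/1
        tuples, treatment 1 first) to probabilities -- missing cells default
        to 0 -- or a dense length-2**k vector in mask order.
        """
        if isinstance(table, Mapping):
            k = None
            cells: dict[int, float] = {}
            for key, val in table.items():
                mask, kk = _table_key_to_mask(key, k)
                k = kk
                cells[mask] = cells.get(mask, 0.0) + float(val)
            if k is None:
                raise ValueError("joint table is empty")
            probs = np.zeros(2**k)
            for mask, val in cells.items():
                probs[mask] = val
        else:
            probs = np.asarray(table, dtype=float)
            n = probs.size
            k = n.bit_length() - 1
            if n < 2 or 2**k != n:
                raise ValueError(f"dense joint table length {n} is not a power of two >= 2")
        if k > MAX_TABLE_K:
            raise ValueError(f"k={k} exceeds the table cap {MAX_TABLE_K}; use the independent form")
        neg = np.flatnonzero(probs < -PROB_TOL)
        if neg.size:
            raise ValueError(
                f"joint table cell {_bitstring(int(neg[0]), k)!r} has negative "
                f"probability {probs[neg[0]]!r}"
            )
        total = float(probs.sum())
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"joint table probabilities sum to {total!r}, expected 1")
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        marginals = cls._marginals_from_probs(probs, k)
        return cls(k=k, form="joint_table", probs=probs, marginals=marginals)

    @classmethod
    def from_moments(
        cls, moments: Mapping[Any, float], k: int
    ) -> "UptakeDistribution":
        """Reconstruct the joint table from ordinary joint moments.

        ``moments`` maps non-empty subsets S of {1..k} (e.g. ``"1,3"``) to
        ``m_S = E[prod_{i in S} T_i]``; singleton moments are the marginal
        uptakes and are required.  Missing higher-order moments default to the
        product of their singletons (independence) with a logged notice.  The
        unique table with those moments follows by inclusion-exclusion::

            p(T_A = 1, T_{A^c} = 0) = sum_{B subseteq A^c} (-1)^|B| m_{A u B}

        An implied negative cell means the moment set is infeasible.
        """
        k = int(k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > MAX_TABLE_K:
            raise ValueError(f"k={k} exceeds the table cap {MAX_TABLE_K}")
        given: dict[int, float] = {}
        for key, val in moments.items():
            subset = _subset_key(key, k)
            given[_mask_of(subset)] = float(val)
        singles = np.empty(k)
        for i in range(k):
            m = given.get(1 << i)
            if m is None:
                raise ValueError(f"singleton moment for treatment {i + 1} is required")
            singles[i] = _check_prob(f"moment m_{{{i + 1}}}", m)
        m_full = np.empty(2**k)
        m_full[0] = 1.0
        defaulted = []
        for mask in range(1, 2**k):
            if mask in given:
                m_full[mask] = given[mask]
            else:
                m_full[mask] = np.prod(singles[[i for i in range(k) if mask >> i & 1]])
                if mask.bit_count() > 1:
                    defaulted.append(mask)
        if defaulted:
            names = ", ".join(
                "{" + ",".join(str(i + 1) for i in range(k) if m >> i & 1) + "}"
                for m in defaulted
            )
            logger.info(
                "moments for subsets %s not supplied; defaulting to the "
                "independence product of their marginals",
                names,
            )
        full = 2**k - 1
        probs = np.empty(2**k)
        for a in range(2**k):
            comp = full & ~a
            acc = 0.0
            sub = comp
            while True:  # enumerate submasks of the complement
                acc += (-1.0) ** sub.bit_count() * m_full[a | sub]
                if sub == 0:
                    break
                sub = (sub - 1) & comp
            probs[a] = acc
        neg = np.flatnonzero(probs < -PROB_TOL)
        if neg.size:
            cell = int(neg[np.argmin(probs[neg])])
            raise ValueError(
                f"moment set is infeasible: implied probability of outcome "
                f"{_bitstring(cell, k)!r} is {probs[cell]!r} < 0"
            )
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        return cls(k=k, form="moments", probs=probs, marginals=singles.copy())

    # -- derived quantities -------------------------------------------------

    @staticmethod
    def _marginals_from_probs(probs: np.ndarray, k: int) -> np.ndarray:
        masks = np.arange(probs.size)
        return np.array([probs[(masks >> i) & 1 == 1].sum() for i in range(k)])

    def prob(self, t: Iterable[int] | str) -> float:
        """Probability of one joint outcome ``t`` (bit-string or 0/1 vector)."""
        mask, _ = _table_key_to_mask(t, self.k)
        if self.probs is not None:
            return float(self.probs[mask])
        bits = np.array([(mask >> i) & 1 for i in range(self.k)], dtype=float)
        return float(np.prod(np.where(bits, self.marginals, 1 - self.marginals)))

    def moment(self, subset: Iterable[int] | str) -> float:
        """Ordinary joint moment ``m_S = E[prod_{i in S} T_i] = P(T_i = 1 for all i in S)``."""
        s = _mask_of(_subset_key(subset, self.k))
        if self.probs is None:  # independent beyond the table cap
            return float(np.prod(self.marginals[[i for i in range(self.k) if s >> i & 1]]))
        masks = np.arange(self.probs.size)
        return float(self.probs[(masks & s) == s].sum())

    def joint_moments(self) -> dict[tuple[int, ...], float]:
        """All 2**k - 1 ordinary joint moments, keyed by sorted 1-based subsets."""
        out: dict[tuple[int, ...], float] = {}
        for r in range(1, self.k + 1):
            for subset in itertools.combinations(range(1, self.k + 1), r):
                out[subset] = self.moment(subset)
        return out

    def pgf(self, x: Sequence[float], *, method: str = "auto") -> float:
        """Probability generating function ``E[x_1^T_1 ... x_k^T_k]`` at ``x``.

        Evaluated at the relative-risk vector this is the population-average
        relative risk, so ``marginal risk = cf * pgf(RR)``.

        ``method`` selects the evaluation path: ``"table"`` sums over the
        outcome table, ``"moments"`` uses the expansion
        ``1 + sum_S m_S prod_{i in S} (x_i - 1)``, ``"product"`` uses the
        independence closed form ``prod_i (1 - u_i (1 - x_i))``, and
        ``"auto"`` picks the cheapest valid path.  All valid paths agree.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape != (self.k,):
            raise ValueError(f"pgf argument has length {x.size}, expected k={self.k}")
        if method == "auto":
            method = "product" if self.form == "independent" else "table"
        if method == "product":
            if self.form != "independent":
                raise ValueError("product form is only valid for independent uptakes")
            return float(np.prod(1.0 - self.marginals * (1.0 - x)))
        if self.probs is None:
            raise ValueError(f"method {method!r} needs the outcome table (k <= {MAX_TABLE_K})")
        if method == "table":
            masks = np.arange(self.probs.size)
            vals = np.ones(self.probs.size)
            for i in range(self.k):
                vals *= np.where((masks >> i) & 1, x[i], 1.0)
            return float(self.probs @ vals)
        if method == "moments":
            acc = 1.0
            for subset, m in self.joint_moments().items():
                acc += m * float(np.prod([x[i - 1] - 1.0 for i in subset]))
            return acc
        raise ValueError(f"unknown pgf method {method!r}")

    # -- comparisons --------------------------------------------------------

    def allclose(self, other: "UptakeDistribution", *, tol: float = PROB_TOL) -> bool:
        if self.k != other.k:
            return False
        if self.probs is not None and other.probs is not None:
            return bool(np.allclose(self.probs, other.probs, atol=tol, rtol=0))
        return bool(np.allclose(self.marginals, other.marginals, atol=tol, rtol=0))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"UptakeDistribution(k={self.k}, form={self.form!r}, marginals={self.marginals})"


# Functional aliases matching the operation names used throughout the docs.

def from_independent(marginals: Sequence[float]) -> UptakeDistribution:
    """Joint uptake law for independent treatments with the given marginals."""
    return UptakeDistribution.independent(marginals)


def from_joint_table(table: Mapping[Any, float] | Sequence[float]) -> UptakeDistribution:
    """Joint uptake law from an explicit outcome-probability table."""
    return UptakeDistribution.from_joint_table(table)


def joint_moments(dist: UptakeDistribution) -> dict[tuple[int, ...], float]:
    """All ordinary joint moments of ``dist``."""
    return dist.joint_moments()


def moments_to_table(moments: Mapping[Any, float], k: int) -> UptakeDistribution:
    """Joint uptake law reconstructed from ordinary joint moments."""
    return UptakeDistribution.from_moments(moments, k)


def pgf(dist: UptakeDistribution, x: Sequence[float]) -> float:
    """Probability generating function of ``dist`` evaluated at ``x``."""
    return dist.pgf(x)


# --------------------------------------------------------------------------
# 4. Classic case-fatality-rate DPP calculations
# --------------------------------------------------------------------------


def dpp_single_from_zero(cf: float, u_t: float, rr: float, n: float) -> float:
    """Deaths prevented by introducing one treatment at uptake ``u_t`` from zero.

    ``DPP = cf * u_t * (1 - rr) * N``: the difference between the expected
    deaths with no treatment and with uptake ``u_t``.
    """
    cf = _check_prob("cf", cf)
    u_t = _check_prob("u_t", u_t)
    if rr < 0:
        raise ValueError(f"rr must be >= 0, got {rr!r}")
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n!r}")
    return cf * u_t * (1.0 - rr) * n


def delta_dpp_single(cf: float, u_b: float, u_t: float, rr: float, n: float) -> float:
    """Extra deaths prevented by raising one treatment's uptake u_b -> u_t.

    ``dDPP = cf * (u_t - u_b) * (1 - rr) * N``; signed, negative when uptake
    falls.
    """
    cf = _check_prob("cf", cf)
    u_b = _check_prob("u_b", u_b)
    u_t = _check_prob("u_t", u_t)
    if rr < 0:
        raise ValueError(f"rr must be >= 0, got {rr!r}")
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n!r}")
    return cf * (u_t - u_b) * (1.0 - rr) * n


def marginal_risk(
    cf: float,
    treatments: Sequence[TreatmentEffect | float],
    dist: UptakeDistribution,
) -> float:
    """Population-average risk of death, ``cf * PGF_T(RR_1, ..., RR_k)``.

    Averages the multiplicative risk model over the joint uptake law; with no
    treatments (or a point mass at all-absent) this is just ``cf``.
    """
    cf = _check_prob("cf", cf)
    rr = _rr_vector(treatments)
    if rr.size == 0:
        return cf
    if rr.size != dist.k:
        raise ValueError(f"{rr.size} treatments but distribution has k={dist.k}")
    return cf * dist.pgf(rr)


def dpp_combination(
    cf: float,
    treatments: Sequence[TreatmentEffect | float],
    target: UptakeDistribution,
    n: float,
) -> float:
    """Deaths prevented by a treatment combination at ``target`` uptake vs none.

    ``DPP = N*cf - N*cf*PGF_target(RR)``; under independent target uptakes
    this equals the closed form ``cf * N * (1 - prod_i (1 - u_i * RRR_i))``.
    """
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n!r}")
    return n * _check_prob("cf", cf) - n * marginal_risk(cf, treatments, target)


def delta_dpp_combination(
    cf: float,
    treatments: Sequence[TreatmentEffect | float],
    baseline: UptakeDistribution,
    target: UptakeDistribution,
    n: float,
) -> float:
    """Extra deaths prevented when joint uptake shifts baseline -> target.

    ``dDPP = cf * N * [PGF_baseline(RR) - PGF_target(RR)]``; under
    independence this is the familiar product-difference form
    ``cf * N * [prod(1 - u_b,i RRR_i) - prod(1 - u_t,i RRR_i)]``.
    """
    cf = _check_prob("cf", cf)
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n!r}")
    rr = _rr_vector(treatments)
    if baseline.k != target.k or rr.size != baseline.k:
        raise ValueError(
            f"mismatched sizes: {rr.size} treatments, baseline k={baseline.k}, "
            f"target k={target.k}"
        )
    return cf * n * (baseline.pgf(rr) - target.pgf(rr))


def biased_cf(cf_true: float, u_b: float, rrr: float) -> float:
    """Observed fatality rate when a single treatment is partially taken up.

    With baseline uptake ``u_b`` the observed rate is
    ``cf~ = cf * (1 - u_b * RRR)`` -- lower than the no-treatment ``cf``, which
    is what biases the classic calculation when ``cf~`` is substituted for it.
    """
    cf_true = _check_prob("cf_true", cf_true)
    u_b = _check_prob("u_b", u_b)
    return cf_true * (1.0 - u_b * rrr)


def biased_cf_multi(
    cf_true: float,
    treatments: Sequence[TreatmentEffect | float],
    baseline: UptakeDistribution,
) -> float:
    """Multi-treatment observed fatality rate, ``cf * PGF_baseline(RR)``."""
    return marginal_risk(cf_true, treatments, baseline)


def underestimation_factor(u_b: float, rrr: float) -> float:
    """Fraction by which the classic method underestimates the single-treatment dDPP.

    Using the observed rate ``cf~`` in place of the true ``cf`` scales the
    single-treatment ``dDPP`` by ``1 - u_b * RRR``, i.e. it is short by the
    factor ``u_b * RRR`` returned here.
    """
    return _check_prob("u_b", u_b) * rrr


# --------------------------------------------------------------------------
# 5. Potential impact fraction engine
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalExposure:
    """A categorical risk factor with baseline and counterfactual level proportions.

    ``p`` and ``p_prime`` are the level proportions before and after the
    distributional shift (each summing to 1); ``rr`` are per-level relative
    risks with the first level as the reference (``rr[0] == 1``).
    """

    p: tuple[float, ...]
    p_prime: tuple[float, ...]
    rr: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, float)
        pp = np.asarray(self.p_prime, float)
        rr = np.asarray(self.rr, float)
        if not (p.size == pp.size == rr.size) or p.size < 2:
            raise ValueError("p, p_prime and rr must share a length of at least 2")
        for name, vec in (("p", p), ("p_prime", pp)):
            if (vec < 0).any():
                raise ValueError(f"{name} has a negative proportion")
            if abs(vec.sum() - 1.0) > PROB_TOL:
                raise ValueError(f"{name} sums to {vec.sum()!r}, expected 1")
        if abs(rr[0] - 1.0) > PROB_TOL:
            raise ValueError(f"reference level must have rr = 1, got {rr[0]!r}")
        if (rr < 0).any():
            raise ValueError("relative risks must be >= 0")


def pif_categorical(exposure: CategoricalExposure) -> float:
    """Potential impact fraction for a shift in a categorical exposure.

    ``PIF = (sum_i P_i RR_i - sum_i P'_i RR_i) / sum_i P_i RR_i``.
    """
    p = np.asarray(exposure.p, float)
    pp = np.asarray(exposure.p_prime, float)
    rr = np.asarray(exposure.rr, float)
    denom = float(p @ rr)
    if denom <= 0:
        raise ValueError("baseline average relative risk is zero; PIF undefined")
    return (denom - float(pp @ rr)) / denom


def pif_single(u_b: float, u_t: float, rr: float) -> float:
    """PIF for one treatment's uptake moving ``u_b -> u_t``.

    The two-level categorical PIF with treatment as a protective exposure
    collapses to ``(u_t - u_b) * RRR / (1 - u_b * RRR)`` with ``RRR = 1 - rr``.
    Signed: negative when uptake decreases.
    """
    u_b = _check_prob("u_b", u_b)
    u_t = _check_prob("u_t", u_t)
    if rr < 0:
        raise ValueError(f"rr must be >= 0, got {rr!r}")
    rrr = 1.0 - rr
    denom = 1.0 - u_b * rrr
    if denom <= 0:
        raise ValueError(f"baseline survival factor 1 - u_b*RRR = {denom!r} <= 0; PIF undefined")
    return (u_t - u_b) * rrr / denom


def pif_independent(
    u_b: Sequence[float],
    u_t: Sequence[float],
    treatments: Sequence[TreatmentEffect | float],
) -> float:
    """PIF for independent multi-treatment uptake shifts (product form).

    ``PIF = [prod_i (1 - u_b,i RRR_i) - prod_i (1 - u_t,i RRR_i)]
    / prod_i (1 - u_b,i RRR_i)``.
    """
    ub = np.atleast_1d(np.asarray(u_b, float))
    ut = np.atleast_1d(np.asarray(u_t, float))
    rr = _rr_vector(treatments)
    if not (ub.size == ut.size == rr.size):
        raise ValueError(
            f"length mismatch: u_b has {ub.size}, u_t has {ut.size}, treatments {rr.size}"
        )
    for name, vec in (("u_b", ub), ("u_t", ut)):
        bad = np.flatnonzero((vec < 0) | (vec > 1))
        if bad.size:
            raise ValueError(f"{name}[{bad[0]}] = {vec[bad[0]]!r} outside [0, 1]")
    rrr = 1.0 - rr
    denom = float(np.prod(1.0 - ub * rrr))
    if denom <= 0:
        raise ValueError("baseline survival product is zero; PIF undefined")
    return (denom - float(np.prod(1.0 - ut * rrr))) / denom


def pif_general(
    baseline: UptakeDistribution,
    target: UptakeDistribution,
    treatments: Sequence[TreatmentEffect | float],
) -> float:
    """PIF for arbitrary (possibly dependent) joint uptake shifts, via the PGF.

    ``PIF = [PGF_baseline(RR) - PGF_target(RR)] / PGF_baseline(RR)``.  The
    case fatality rate cancels from numerator and denominator, which is the
    point of the PIF route: only the uptake laws and relative risks enter.
    """
    rr = _rr_vector(treatments)
    if baseline.k != target.k or rr.size != baseline.k:
        raise ValueError(
            f"mismatched sizes: {rr.size} treatments, baseline k={baseline.k}, "
            f"target k={target.k}"
        )
    pgf_b = baseline.pgf(rr)
    if pgf_b <= 0:
        raise ValueError("baseline PGF at RR is zero (guaranteed survival); PIF undefined")
    return (pgf_b - target.pgf(rr)) / pgf_b


def delta_dpp_from_pif(pif: float, deaths: float) -> float:
    """Deaths prevented or postponed from a PIF: ``dDPP = PIF * d``."""
    if deaths < 0:
        raise ValueError(f"deaths must be >= 0, got {deaths!r}")
    return pif * deaths


@dataclass
class Stratum:
    """A population slice with its own deaths and (optionally) parameters.

    ``n`` is the eligible diseased population, ``deaths`` the observed death
    count under baseline uptake.  A stratum may override the scenario-level
    treatments and uptake laws; unset fields inherit the scenario defaults.
    """

    label: str
    n: int
    deaths: float | None = None
    cf: float | None = None
    treatments: tuple[TreatmentEffect, ...] | None = None
    baseline: UptakeDistribution | None = None
    target: UptakeDistribution | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"stratum {self.label!r}: N must be >= 1, got {self.n!r}")
        if self.deaths is not None and not 0 <= self.deaths <= self.n:
            raise ValueError(
                f"stratum {self.label!r}: deaths must lie in [0, N], got {self.deaths!r}"
            )
        if self.cf is not None:
            _check_prob(f"stratum {self.label!r} cf", self.cf)


@dataclass(frozen=True)
class StratumImpact:
    """Per-stratum PIF result row."""

    label: str
    pif: float
    deaths: float
    delta_dpp: float


def stratified_delta_dpp(
    strata: Sequence[Stratum],
    *,
    treatments: Sequence[TreatmentEffect | float] | None = None,
    baseline: UptakeDistribution | None = None,
    target: UptakeDistribution | None = None,
) -> tuple[float, list[StratumImpact]]:
    """Total ``dDPP = sum_j PIF_j * d_j`` across strata, with per-stratum rows.

    Each stratum uses its own treatments/uptake laws where set, otherwise the
    ones passed here.  Returns ``(total, rows)``.
    """
    if not strata:
        raise ValueError("at least one stratum is required")
    rows: list[StratumImpact] = []
    for s in strata:
        tr = s.treatments if s.treatments is not None else treatments
        b = s.baseline if s.baseline is not None else baseline
        t = s.target if s.target is not None else target
        if tr is None or b is None or t is None:
            raise ValueError(f"stratum {s.label!r} lacks treatments or uptake laws")
        if s.deaths is None:
            raise ValueError(f"stratum {s.label!r} lacks an observed death count")
        p = pif_general(b, t, tr)
        rows.append(StratumImpact(s.label, p, float(s.deaths), p * float(s.deaths)))
    total = float(sum(r.delta_dpp for r in rows))
    return total, rows


def mortality_reduction(delta_dpp: float, total_deaths: float) -> float:
    """Percent reduction in disease mortality: ``100 * dDPP / d``."""
    if total_deaths <= 0:
        raise ValueError(f"total deaths must be > 0, got {total_deaths!r}")
    return 100.0 * delta_dpp / total_deaths


def percent_difference(dpp_classic: float, dpp_pif: float) -> float:
    """Percent by which the PIF-based dDPP exceeds the classic one.

    ``100 * (dDPP_PIF - dDPP_classic) / dDPP_classic``, the comparison
    convention used in method-contrast tables.
    """
    if dpp_classic == 0:
        raise ValueError("classic dDPP is zero; percent difference undefined")
    return 100.0 * (dpp_pif - dpp_classic) / dpp_classic


# --------------------------------------------------------------------------
# 6. Individual-level cohort simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort of individuals under the multiplicative risk model.

    ``treatments`` is the (n, k) 0/1 matrix of treatment receipt; ``deaths``
    the length-n 0/1 death indicator.  Generating parameters are retained so
    analytic quantities can be recomputed alongside empirical ones.
    """

    treatments: np.ndarray
    deaths: np.ndarray
    cf_true: float
    effects: tuple[TreatmentEffect, ...]
    seed: int

    @property
    def n(self) -> int:
        return int(self.deaths.size)

    @property
    def k(self) -> int:
        return int(self.treatments.shape[1])

    @property
    def death_rate(self) -> float:
        """Empirical marginal risk of death."""
        return float(self.deaths.mean())

    def uptake_frequencies(self) -> np.ndarray:
        """Empirical joint outcome frequencies in mask order (length 2**k)."""
        masks = (self.treatments.astype(np.int64) << np.arange(self.k)).sum(axis=1)
        return np.bincount(masks, minlength=2**self.k) / self.n

    def to_dataframe(self) -> pd.DataFrame:
        """Flat table with columns ``t_1 .. t_k, death``."""
        cols = {f"t_{i + 1}": self.treatments[:, i] for i in range(self.k)}
        cols["death"] = self.deaths
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_cohort(
    n: int,
    cf_true: float,
    treatments: Sequence[TreatmentEffect | float],
    dist: UptakeDistribution,
    seed: int,
) -> SimulatedCohort:
    """Simulate ``n`` individuals: draw T from ``dist``, then death ~ Bernoulli(R(T)).

    The conditional risk is ``R(t) = cf_true * prod_i rr_i**t_i``; every cell
    risk must be a valid probability.  A seed is mandatory -- there is no
    hidden global randomness -- and identical seeds reproduce the cohort
    exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    cf_true = _check_prob("cf_true", cf_true)
    effects = _as_effects(treatments)
    rr = np.array([t.rr for t in effects])
    k = rr.size
    if k != dist.k:
        raise ValueError(f"{k} treatments but distribution has k={dist.k}")
    masks = np.arange(2**k)
    bits = (masks[:, None] >> np.arange(k)) & 1
    cell_risk = cf_true * np.prod(np.where(bits, rr, 1.0), axis=1)
    over = np.flatnonzero(cell_risk > 1.0 + 1e-12)
    if over.size:
        cells = ", ".join(_bitstring(int(m), k) for m in over)
        raise ValueError(
            f"risk model exceeds 1 for treatment pattern(s) {cells}: "
            f"cf_true * prod(rr**t) must be a probability"
        )
    rng = np.random.default_rng(seed)
    if dist.probs is not None:
        drawn = rng.choice(2**k, size=n, p=dist.probs)
        t = ((drawn[:, None] >> np.arange(k)) & 1).astype(np.uint8)
    else:  # independent beyond the table cap
        t = (rng.random((n, k)) < dist.marginals).astype(np.uint8)
        drawn = (t.astype(np.int64) << np.arange(k)).sum(axis=1)
    death = (rng.random(n) < cell_risk[drawn]).astype(np.uint8)
    return SimulatedCohort(
        treatments=t, deaths=death, cf_true=cf_true, effects=effects, seed=int(seed)
    )


def empirical_pif(baseline_cohort: SimulatedCohort, target_cohort: SimulatedCohort) -> float:
    """Empirical PIF from two simulated arms: ``(rate_b - rate_t) / rate_b``."""
    rate_b = baseline_cohort.death_rate
    if rate_b == 0:
        raise ValueError("baseline cohort has no deaths; empirical PIF undefined")
    return (rate_b - target_cohort.death_rate) / rate_b


def random_scenario(
    seed: int,
    *,
    k_max: int = 4,
    forms: Sequence[str] = ("independent", "joint_table"),
    n_range: tuple[int, int] = (200, 5000),
) -> "Scenario":
    """Generate a random valid scenario for property testing and validation.

    Treatments get relative risks in (0, 1]; baseline and target joint uptake
    laws are drawn either as independent marginals or as a Dirichlet-random
    joint table (allowing dependence); the single stratum carries a true case
    fatality rate and no observed death count (imputed on run).
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, k_max + 1))
    effects = tuple(
        TreatmentEffect(id=f"t{i + 1}", rr=float(rng.uniform(0.05, 1.0))) for i in range(k)
    )

    def draw_dist() -> UptakeDistribution:
        form = forms[int(rng.integers(len(forms)))]
        if form == "independent":
            return UptakeDistribution.independent(rng.uniform(0.0, 1.0, size=k))
        return UptakeDistribution.from_joint_table(rng.dirichlet(np.ones(2**k)))

    n = int(rng.integers(n_range[0], n_range[1] + 1))
    cf = float(rng.uniform(0.02, 0.5))
    return Scenario(
        name=f"random-{seed}",
        treatments=list(effects),
        baseline=draw_dist(),
        target=draw_dist(),
        strata=[Stratum(label="all", n=n, cf=cf)],
        cf_interpretation="true",
    )


# --------------------------------------------------------------------------
# 7. Scenario files, runner and reports
# --------------------------------------------------------------------------


@dataclass
class Scenario:
    """A fully resolved impact scenario: treatments, uptake shift, strata."""

    name: str
    treatments: list[TreatmentEffect]
    baseline: UptakeDistribution
    target: UptakeDistribution
    strata: list[Stratum]
    cf: float | None = None
    cf_interpretation: Literal["biased", "true"] = "biased"
    decimals: int = 2


# ---- fail-closed file schema (unknown keys rejected) ----------------------


class _UptakeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    form: Literal["independent", "joint_table", "moments"]
    marginals: list[float] | None = None
    table: dict[str, float] | None = None
    moments: dict[str, float] | None = None
    k: int | None = None

    @model_validator(mode="after")
    def _check_payload(self) -> "_UptakeSpec":
        need = {"independent": "marginals", "joint_table": "table", "moments": "moments"}[self.form]
        if getattr(self, need) is None:
            raise ValueError(f"uptake form {self.form!r} requires the {need!r} field")
        if self.form == "moments" and self.k is None:
            raise ValueError("uptake form 'moments' requires the 'k' field")
        return self

    def build(self) -> UptakeDistribution:
        if self.form == "independent":
            return UptakeDistribution.independent(self.marginals)
        if self.form == "joint_table":
            return UptakeDistribution.from_joint_table(self.table)
        return UptakeDistribution.from_moments(self.moments, self.k)


class _TreatmentSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    rr: float | None = None
    rrr: float | None = None

    @model_validator(mode="after")
    def _check_effect(self) -> "_TreatmentSpec":
        if (self.rr is None) == (self.rrr is None):
            raise ValueError(f"treatment {self.id!r}: give exactly one of rr or rrr")
        return self

    def build(self) -> TreatmentEffect:
        if self.rr is not None:
            return TreatmentEffect(id=self.id, rr=self.rr)
        return TreatmentEffect.from_rrr(self.id, self.rrr)


class _StratumSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    label: str
    n: int = Field(alias="N", ge=1)
    deaths: float | None = Field(default=None, ge=0)
    cf: float | None = Field(default=None, ge=0, le=1)
    treatments: list[_TreatmentSpec] | None = None
    baseline_uptake: _UptakeSpec | None = None
    target_uptake: _UptakeSpec | None = None

    @model_validator(mode="after")
    def _check_deaths(self) -> "_StratumSpec":
        if self.deaths is not None and self.deaths > self.n:
            raise ValueError(f"stratum {self.label!r}: deaths exceed N")
        return self


class _OptionsSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cf_interpretation: Literal["biased", "true"] = "biased"
    decimals: int = Field(default=2, ge=0, le=12)


class _ScenarioSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: Literal[1]
    name: str
    treatments: list[_TreatmentSpec] = Field(min_length=1)
    baseline_uptake: _UptakeSpec
    target_uptake: _UptakeSpec
    cf: float | None = Field(default=None, ge=0, le=1)
    strata: list[_StratumSpec] = Field(min_length=1)
    options: _OptionsSpec = Field(default_factory=_OptionsSpec)

    @model_validator(mode="after")
    def _check_ids(self) -> "_ScenarioSpec":
        ids = [t.id for t in self.treatments]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate treatment ids: {ids}")
        return self


def _build_scenario(spec: _ScenarioSpec) -> Scenario:
    treatments = [t.build() for t in spec.treatments]
    baseline = spec.baseline_uptake.build()
    target = spec.target_uptake.build()
    k = len(treatments)
    if baseline.k != k or target.k != k:
        raise ValueError(
            f"scenario {spec.name!r}: {k} treatments but uptake laws have "
            f"k={baseline.k} (baseline), k={target.k} (target)"
        )
    strata = []
    for s in spec.strata:
        strata.append(
            Stratum(
                label=s.label,
                n=s.n,
                deaths=s.deaths,
                cf=s.cf,
                treatments=tuple(t.build() for t in s.treatments) if s.treatments else None,
                baseline=s.baseline_uptake.build() if s.baseline_uptake else None,
                target=s.target_uptake.build() if s.target_uptake else None,
            )
        )
    return Scenario(
        name=spec.name,
        treatments=treatments,
        baseline=baseline,
        target=target,
        strata=strata,
        cf=spec.cf,
        cf_interpretation=spec.options.cf_interpretation,
        decimals=spec.options.decimals,
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario file (YAML or JSON).

    Unknown keys are rejected; schema violations raise pydantic's
    ``ValidationError`` with field paths; probability-range violations raise
    ``ValueError`` from the distribution constructors.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    spec = _ScenarioSpec.model_validate(raw)
    return _build_scenario(spec)


def example_scenario(name: str = "synthetic_example") -> Scenario:
    """Load one of the packaged example scenarios.

    ``"synthetic_example"``: the two-treatment worked example (N=2500, 750
    baseline deaths, uptakes (0.5, 0.6) -> (0.8, 0.8), RRR (0.07, 0.1),
    independent uptakes).  ``"dependent_demo"``: a three-treatment scenario
    with positively dependent baseline uptake supplied as joint moments.
    """
    ref = resources.files("pifdpp").joinpath(f"fixtures/{name}.yaml")
    with resources.as_file(ref) as path:
        return load_scenario(path)


# ---- runner ---------------------------------------------------------------


@dataclass(frozen=True)
class ResultRow:
    """One line of a method-comparison report.

    ``treatment`` is a single treatment id for attribution rows (one uptake
    changed, others held at baseline) or ``"(joint)"`` for the row evaluating
    the full combination; totals sum only the joint rows.
    """

    stratum: str
    treatment: str
    pif: float
    deaths: float
    dpp_classic: float
    dpp_pif: float
    pct_reduction_classic: float
    pct_reduction_pif: float
    pct_difference: float | None


_COLUMNS = [
    "stratum",
    "treatment",
    "pif",
    "deaths",
    "dpp_classic",
    "dpp_pif",
    "pct_reduction_classic",
    "pct_reduction_pif",
    "pct_difference",
]


@dataclass(frozen=True)
class ImpactResult:
    """Full scenario result: per-stratum rows (joint + attribution) and totals."""

    scenario: str
    rows: tuple[ResultRow, ...]
    total: ResultRow

    def joint_rows(self) -> list[ResultRow]:
        return [r for r in self.rows if r.treatment == "(joint)"]

    def to_dataframe(self, include_total: bool = True) -> pd.DataFrame:
        rows = list(self.rows) + ([self.total] if include_total else [])
        return pd.DataFrame([vars(r) for r in rows], columns=_COLUMNS)

    def to_dict(self) -> dict[str, Any]:
        return {
            "scenario": self.scenario,
            "rows": [vars(r) for r in self.rows],
            "total": vars(self.total),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ImpactResult":
        return cls(
            scenario=d["scenario"],
            rows=tuple(ResultRow(**r) for r in d["rows"]),
            total=ResultRow(**d["total"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "ImpactResult":
        return cls.from_dict(json.loads(s))


def _resolve_deaths_and_cf(
    stratum: Stratum,
    scenario: Scenario,
    pgf_baseline: float,
) -> tuple[float, float]:
    """Resolve (deaths, classic-method cf) for one stratum.

    The ``cf_interpretation`` flag declares what a supplied cf (or the d/N
    estimate) means: ``"biased"`` -- it is the observed fatality rate under
    baseline uptake, used as-is by the classic path (the practice whose bias
    this package quantifies); ``"true"`` -- it is the no-treatment rate, so
    d/N estimates are deconvolved by PGF_baseline(RR) before classic use.
    """
    interp = scenario.cf_interpretation
    cf_given = stratum.cf if stratum.cf is not None else scenario.cf
    deaths = stratum.deaths
    if deaths is None:
        if cf_given is None:
            raise ValueError(
                f"stratum {stratum.label!r}: either deaths or a case fatality rate is required"
            )
        expected = stratum.n * cf_given * (pgf_baseline if interp == "true" else 1.0)
        deaths = float(round(expected))
        logger.info(
            "stratum %r: deaths imputed as %s from cf=%s (%s interpretation)",
            stratum.label, deaths, cf_given, interp,
        )
    elif cf_given is not None:
        expected = stratum.n * cf_given * (pgf_baseline if interp == "true" else 1.0)
        if expected > 0 and abs(deaths - expected) / expected > 0.01:
            logger.warning(
                "stratum %r: observed deaths %s disagree with cf-implied %s by more "
                "than 1%%; deaths drive the PIF path, cf the classic path",
                stratum.label, deaths, expected,
            )
    if cf_given is not None:
        cf_classic = cf_given
    elif interp == "true":
        cf_classic = deaths / stratum.n / pgf_baseline
    else:
        cf_classic = deaths / stratum.n
    return float(deaths), float(cf_classic)


def run_scenario(scenario: Scenario) -> ImpactResult:
    """Run both estimation methods over every stratum of a scenario.

    Per stratum, the joint row evaluates the whole treatment combination:
    classic ``dDPP = cf * N * [PGF_b(RR) - PGF_t(RR)]`` and PIF-based
    ``dDPP = PIF * d``.  Attribution rows shift one treatment's marginal
    uptake at a time (others held at baseline) using the single-treatment
    formulas; they are reported for inspection but never summed into totals,
    since summing per-treatment effects overstates the joint effect.
    """
    rows: list[ResultRow] = []
    tot_deaths = tot_classic = tot_pif = 0.0
    for s in scenario.strata:
        tr = s.treatments if s.treatments is not None else tuple(scenario.treatments)
        b = s.baseline if s.baseline is not None else scenario.baseline
        t = s.target if s.target is not None else scenario.target
        rr = _rr_vector(tr)
        pgf_b = b.pgf(rr)
        deaths, cf_classic = _resolve_deaths_and_cf(s, scenario, pgf_b)
        p = pif_general(b, t, tr)
        dpp_c = delta_dpp_combination(cf_classic, tr, b, t, s.n)
        dpp_p = delta_dpp_from_pif(p, deaths)
        rows.append(
            ResultRow(
                stratum=s.label,
                treatment="(joint)",
                pif=p,
                deaths=deaths,
                dpp_classic=dpp_c,
                dpp_pif=dpp_p,
                pct_reduction_classic=mortality_reduction(dpp_c, deaths) if deaths else 0.0,
                pct_reduction_pif=mortality_reduction(dpp_p, deaths) if deaths else 0.0,
                pct_difference=percent_difference(dpp_c, dpp_p) if dpp_c != 0 else None,
            )
        )
        if len(tr) > 1:
            for i, eff in enumerate(_as_effects(tr)):
                u_ib = float(b.marginals[i])
                u_it = float(t.marginals[i])
                p_i = pif_single(u_ib, u_it, eff.rr)
                dpp_ci = delta_dpp_single(cf_classic, u_ib, u_it, eff.rr, s.n)
                dpp_pi = delta_dpp_from_pif(p_i, deaths)
                rows.append(
                    ResultRow(
                        stratum=s.label,
                        treatment=eff.id,
                        pif=p_i,
                        deaths=deaths,
                        dpp_classic=dpp_ci,
                        dpp_pif=dpp_pi,
                        pct_reduction_classic=mortality_reduction(dpp_ci, deaths) if deaths else 0.0,
                        pct_reduction_pif=mortality_reduction(dpp_pi, deaths) if deaths else 0.0,
                        pct_difference=percent_difference(dpp_ci, dpp_pi) if dpp_ci != 0 else None,
                    )
                )
        tot_deaths += deaths
        tot_classic += dpp_c
        tot_pif += dpp_p
    total = ResultRow(
        stratum="(total)",
        treatment="(joint)",
        pif=tot_pif / tot_deaths if tot_deaths else 0.0,
        deaths=tot_deaths,
        dpp_classic=tot_classic,
        dpp_pif=tot_pif,
        pct_reduction_classic=mortality_reduction(tot_classic, tot_deaths) if tot_deaths else 0.0,
        pct_reduction_pif=mortality_reduction(tot_pif, tot_deaths) if tot_deaths else 0.0,
        pct_difference=percent_difference(tot_classic, tot_pif) if tot_classic != 0 else None,
    )
    return ImpactResult(scenario=scenario.name, rows=tuple(rows), total=total)


def render_report(result: ImpactResult, fmt: str = "text") -> str:
    """Render an :class:`ImpactResult`.

    ``"text"``: fixed-width table, DPP and percents to 2 decimals, PIF to 5
    (matching the precision such tables are conventionally printed at).
    ``"csv"`` and ``"json"``: full precision, machine-readable, deterministic.
    """
    if fmt == "json":
        return result.to_json()
    df = result.to_dataframe(include_total=True)
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "text":
        shown = df.copy()
        shown["pif"] = shown["pif"].map(lambda v: f"{round_half_up(v, 5):.5f}")
        shown["deaths"] = shown["deaths"].map(lambda v: f"{v:g}")
        for col in (
            "dpp_classic",
            "dpp_pif",
            "pct_reduction_classic",
            "pct_reduction_pif",
            "pct_difference",
        ):
            shown[col] = shown[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v))
                else f"{round_half_up(v, 2):.2f}"
            )
        header = f"scenario: {result.scenario}"
        return header + "\n" + shown.to_string(index=False) + "\n"
    raise ValueError(f"unknown report format {fmt!r} (expected text, csv or json)")
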