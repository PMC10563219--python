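"""Unified selection scores: threshold, renormalize and combine
per-trait bootstrap selection probabilities into one score per variant.

The construction equalizes the probability mass that every trait
contributes.  Let ``S_k`` be trait k's sum of selection probabilities and
``eta`` the minimum (by default) of the ``S_k``.  Within each trait the
probabilities are sorted descending and cut at the smallest prefix whose
sum reaches ``eta``; the value at the cut is the trait threshold ``tau_k``.
Entries at or above ``tau_k`` survive and are rescaled by ``eta / S_tilde``
(``S_tilde`` = sum of survivors, >= eta when ties straddle the cut) so each
trait's surviving mass is exactly ``eta``.  A variant's unified score is the
sum of its adjusted probabilities across traits; it ranges from 0 to q and,
for strongly associated variants, approaches the number of traits the
variant is associated with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np

from uniss.selprob import SelectionProbabilityMatrix

__all__ = [
    "UnifiedScoreResult",
    "trait_sum",
    "threshold_index",
    "adjust_trait",
    "unified_scores",
    "write_scores",
]

EtaRule = Literal["min", "max", "median"]

_SUM_TOL = 1e-9  # slack when asserting the per-trait adjusted-sum identity


class ContractViolation(ValueError):
    """An argument combination the score construction rules out."""


@dataclass
class UnifiedScoreResult:
    """Per-variant unified scores plus the construction internals."""

    pi: np.ndarray  # length p
    eta: float
    tau: np.ndarray  # length q
    adjusted: np.ndarray  # p x q
    order: np.ndarray  # variant indices, descending score, ties by index
    eta_rule: EtaRule
    variant_ids: Optional[list[str]] = None
    trait_ids: Optional[list[str]] = None

    def ranking(self) -> np.ndarray:
        """Rank of each variant (1 = highest score; ties share the index order)."""
        ranks = np.empty_like(self.order)
        ranks[self.order] = np.arange(1, len(self.order) + 1)
        return ranks


def trait_sum(s: np.ndarray) -> float:
    """Sum of one trait's selection probabilities over the p variants."""
    s = np.asarray(s, dtype=np.float64)
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("selection probabilities must lie in [0, 1]")
    return float(s.sum())


def threshold_index(s_sorted_desc: np.ndarray, eta: float) -> int:
    """Smallest prefix length J of a descending vector whose sum reaches eta.

    The comparison is a plain ``>=`` with no epsilon slack, so borderline
    cumulative sums resolve reproducibly.  ``eta = 0`` returns J = 1 (the
    minimum over non-empty prefixes).
    """
    s = np.asarray(s_sorted_desc, dtype=np.float64)
    if s.size == 0:
        raise ContractViolation("empty probability vector")
    if np.any(np.diff(s) > 0):
        raise ValueError("vector must be sorted in descending order")
    cumsum = np.cumsum(s)
    if eta > cumsum[-1]:
        # summation-order rounding can leave eta one ulp above the cumsum
        if eta <= cumsum[-1] + 1e-9 * max(1.0, eta):
            return int(s.size)
        raise ContractViolation(
            f"eta={eta} exceeds the total probability mass {cumsum[-1]}"
        )
    return int(np.argmax(cumsum >= eta)) + 1


def adjust_trait(s: np.ndarray, eta: float) -> tuple[float, np.ndarray]:
    """Threshold and renormalize one trait's probabilities to mass ``eta``.

    Returns ``(tau, adjusted)``: entries below ``tau`` are zeroed, the rest
    scaled by ``eta / S_tilde``.  When ``eta`` exceeds the trait's total mass
    (possible under the max/median eta rules) every nonzero entry survives
    and the trait is upweighted by ``eta / S_k``.
    """
    s = np.asarray(s, dtype=np.float64)
    total = trait_sum(s)
    if eta < 0.0:
        raise ContractViolation("eta must be non-negative")
    if eta > total + 1e-9 * max(1.0, eta):
        if total == 0.0:
            raise ContractViolation("cannot spread positive mass over an all-zero trait")
        survivors = s > 0.0
        tau = float(s[survivors].min())
    else:
        s_sorted = np.sort(s)[::-1]
        J = threshold_index(s_sorted, eta)
        tau = float(s_sorted[J - 1])
        survivors = s >= tau
    s_tilde = float(s[survivors].sum())
    if s_tilde == 0.0:
        # only reachable with eta == 0 on an all-zero vector
        return tau, np.zeros_like(s)
    # (s * eta) / s_tilde: this association keeps the reference worked example
    # (0.7/1.1 etc. at eta = 1) bit-exact
    adjusted = np.where(survivors, s * eta / s_tilde, 0.0)
    return tau, adjusted


def unified_scores(
    S: Union[SelectionProbabilityMatrix, np.ndarray],
    eta_rule: EtaRule = "min",
) -> UnifiedScoreResult:
    """Unified selection score per variant from a p x q probability matrix.

    ``eta`` is the minimum of the per-trait sums by default; "max" and
    "median" upweight sparse traits instead.  Variants are ranked by
    descending score with ties broken by ascending index (stable).
    """
    if isinstance(S, SelectionProbabilityMatrix):
        values, variant_ids, trait_ids = S.values, S.variant_ids, S.trait_ids
    else:
        values = np.asarray(S, dtype=np.float64)
        variant_ids = trait_ids = None
    if values.ndim != 2:
        raise ValueError("probability matrix must be 2-dimensional")
    p, q = values.shape

    sums = values.sum(axis=0)
    if eta_rule == "min":
        eta = float(sums.min())
    elif eta_rule == "max":
        eta = float(sums.max())
    elif eta_rule == "median":
        eta = float(np.median(sums))
    else:
        raise ValueError(f"unknown eta_rule {eta_rule!r}")

    if eta == 0.0 and eta_rule == "min" and sums.max() > 0.0:
        warnings.warn(
            "some trait selected nothing, so eta = 0 forces all unified scores "
            "to zero; consider eta_rule='median' (raw column sums: "
            f"{np.array2string(sums, precision=3)})",
            RuntimeWarning,
            stacklevel=2,
        )

    tau = np.empty(q)
    adjusted = np.empty_like(values)
    for k in range(q):
        if sums[k] == 0.0 and eta == 0.0:
            tau[k], adjusted[:, k] = 0.0, 0.0
            continue
        tau[k], adjusted[:, k] = adjust_trait(values[:, k], eta)
        if abs(adjusted[:, k].sum() - eta) > max(_SUM_TOL, _SUM_TOL * eta):
            raise AssertionError("adjusted column mass deviates from eta")

    pi = adjusted.sum(axis=1)
    order = np.argsort(-pi, kind="stable")
    return UnifiedScoreResult(
        pi=pi,
        eta=eta,
        tau=tau,
        adjusted=adjusted,
        order=order,
        eta_rule=eta_rule,
        variant_ids=variant_ids,
        trait_ids=trait_ids,
    )


def write_scores(path, result: UnifiedScoreResult) -> None:
    """TSV output: variant, score, rank and per-trait adjusted contributions."""
    p, q = result.adjusted.shape
    variant_ids = result.variant_ids or [f"snp_{j + 1}" for j in range(p)]
    trait_ids = result.trait_ids or [f"trait_{k + 1}" for k in range(q)]
    ranks = result.ranking()
    with open(path, "w") as fh:
        fh.write(f"#eta_rule\t{result.eta_rule}\n")
        fh.write(f"#eta\t{result.eta:.10g}\n")
        fh.write("#tau_k\t" + "\t".join(f"{t:.10g}" for t in result.tau) + "\n")
        header = "\t".join(f"adj_{t}" for t in trait_ids)
        fh.write(f"variant_id\tscore\trank\t{header}\n")
        for j in result.order:
            row = "\t".join(f"{v:.10g}" for v in result.adjusted[j])
            fh.write(f"{variant_ids[j]}\t{result.pi[j]:.10g}\t{ranks[j]}\t{row}\n")
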