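"""Summary statistics over propagation results.

Covers the four question families of the study design: how accurate are the
fitted exchange rates (RSE distributions), how wide are the propagated
growth-rate distributions (quantiles/IQR of mu/mu_ref over feasible draws),
which metabolite groups drive the error (top-k by RSE, essential amino acids
near their biomass requirement, random control groupings), and how reliably
can two cell lines be ranked by growth (all-pairs comparison of two draw
sets).

Conventions: quantiles use the median-unbiased estimator; draws whose fit
did not converge are excluded from RSE summaries (and counted); pairs with
an infeasible member are dropped from the ranking denominator (and counted);
exact growth-rate ties are conservatively scored as incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fluxprop.model_core import MetabolicNetwork
from fluxprop.propagation import PropagationResult
from fluxprop.reference_fba import ReferenceState

_Q = dict(method="median_unbiased")


@dataclass(frozen=True)
class RankingSummary:
    """All-pairs growth comparison between two cell lines."""

    n_pairs_total: int
    n_pairs_compared: int  # both members feasible
    p_correct: float  # truly faster line predicted faster (ties incorrect)
    tie_rate: float
    normalized_diff_quantiles: dict[str, float]  # of (mu_A - mu_B)/delta_mu_true


@dataclass(frozen=True)
class GroupAssignment:
    """Disjoint metabolite groups with optional per-group RSDs."""

    groups: Mapping[str, frozenset]
    rsd: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        seen: set = set()
        for label, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"group {label!r} overlaps earlier groups on {sorted(overlap)}")
            seen |= set(members)

    def to_rsd_map(self) -> dict[frozenset, float]:
        if self.rsd is None:
            raise ValueError("no per-group RSDs assigned")
        return {frozenset(m): self.rsd[lab] for lab, m in self.groups.items()}


def summarize_rse(result: PropagationResult) -> pd.DataFrame:
    """Per-metabolite RSE quartiles over converged draws.

    Returns a frame indexed by metabolite with columns ``median_rse``,
    ``q1_rse``, ``q3_rse``, ``n_converged``, ``n_total`` and the reference
    rate ``q_ref``.
    """
    rows = {}
    for met in result.q_hat.columns:
        ok = result.converged[met].to_numpy()
        q = result.q_hat[met].to_numpy()[ok]
        se = result.se_q[met].to_numpy()[ok]
        nonzero = q != 0
        rse_vals = se[nonzero] / np.abs(q[nonzero])
        if rse_vals.size == 0:
            raise ValueError(f"{met}: no converged fits to summarize")
        rows[met] = {
            "median_rse": float(np.quantile(rse_vals, 0.5, **_Q)),
            "q1_rse": float(np.quantile(rse_vals, 0.25, **_Q)),
            "q3_rse": float(np.quantile(rse_vals, 0.75, **_Q)),
            "n_converged": int(ok.sum()),
            "n_total": int(ok.size),
            "q_ref": float(result.reference.rates_complete[met]),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metabolite"
    return out


def low_uptake_essential_set(
    reference: ReferenceState,
    network: MetabolicNetwork,
    factor: float = 1.5,
) -> frozenset[str]:
    """Essential amino acids consumed below ``factor`` x biomass requirement.

    The biomass requirement of amino acid i is mu_ref * b_i with b_i its
    coefficient in the biomass reaction; the set is
    {i essential : |q_i| < factor * mu_ref * b_i}.  These are the uptakes
    used (almost) exclusively for biomass synthesis, whose measurement
    accuracy dominates growth-prediction quality.
    """
    b = network.biomass_coefficients
    out = set()
    for met in sorted(network.essential_set):
        if met not in reference.rates_complete:
            continue
        if met not in b:
            raise KeyError(f"essential metabolite {met!r} has no biomass coefficient")
        if abs(reference.rates_complete[met]) < factor * reference.mu_ref * b[met]:
            out.add(met)
    return frozenset(out)


def top_k_by_rse(rse_summary: pd.DataFrame, k: int = 7) -> frozenset[str]:
    """The k metabolites with largest median RSE.

    Ties are broken toward the smaller |q_ref| (the more error-prone rate).
    """
    if k > len(rse_summary):
        raise ValueError(f"k={k} exceeds the {len(rse_summary)} summarized metabolites")
    if k == 0:
        return frozenset()
    ranked = rse_summary.assign(_absq=rse_summary["q_ref"].abs()).sort_values(
        ["median_rse", "_absq"], ascending=[False, True], kind="mergesort"
    )
    return frozenset(ranked.index[:k])


def growth_ratio_summary(result: PropagationResult, reference: ReferenceState | None = None) -> dict:
    """Quantiles and IQR of mu_fba / mu_ref over feasible draws."""
    reference = reference or result.reference
    mu = result.mu_fba[result.feasible]
    if mu.size < 2:
        raise ValueError("need at least 2 feasible draws to summarize growth ratios")
    ratios = mu / reference.mu_ref
    q = {f"q{int(p*100)}": float(np.quantile(ratios, p, **_Q)) for p in (0.05, 0.25, 0.5, 0.75, 0.95)}
    return {
        "feasible_fraction": result.feasible_fraction,
        "iqr": q["q75"] - q["q25"],
        "quantiles": q,
        "n_feasible": int(mu.size),
    }


def pairwise_ranking(
    result_a: PropagationResult,
    result_b: PropagationResult,
    true_sign: int | None = None,
    delta_mu_true: float | None = None,
) -> RankingSummary:
    """Compare two draw sets over all feasible x feasible pairs.

    ``true_sign`` is the sign of the true growth difference mu_A - mu_B
    (taken from the references when omitted); ``delta_mu_true`` normalizes
    the predicted differences.  A zero true difference has no defined
    normalization and raises.
    """
    if delta_mu_true is None:
        delta_mu_true = result_a.reference.mu_ref - result_b.reference.mu_ref
    if delta_mu_true == 0:
        raise ValueError("true growth difference is zero; ranking undefined")
    if true_sign is None:
        true_sign = int(np.sign(delta_mu_true))
    mu_a = result_a.mu_fba[result_a.feasible]
    mu_b = result_b.mu_fba[result_b.feasible]
    if mu_a.size == 0 or mu_b.size == 0:
        raise ValueError("both results need at least one feasible draw")
    n_total = result_a.n_draws * result_b.n_draws
    diff = mu_a[:, None] - mu_b[None, :]
    n_comp = diff.size
    correct = int((np.sign(diff) == true_sign).sum())
    ties = int((diff == 0).sum())
    norm = (diff / delta_mu_true).ravel()
    quantiles = {f"q{int(p*100)}": float(np.quantile(norm, p, **_Q)) for p in (0.05, 0.25, 0.5, 0.75, 0.95)}
    return RankingSummary(
        n_pairs_total=n_total,
        n_pairs_compared=n_comp,
        p_correct=correct / n_comp,
        tie_rate=ties / n_comp,
        normalized_diff_quantiles=quantiles,
    )


def random_grouping(metabolites: Iterable[str], sizes: Sequence[int], seed: int) -> GroupAssignment:
    """Uniformly random partition of the metabolites into groups of given sizes."""
    mets = list(metabolites)
    if sum(sizes) != len(mets):
        raise ValueError(f"group sizes {list(sizes)} do not sum to {len(mets)} metabolites")
    rng = np.random.default_rng(seed)
    perm = [mets[i] for i in rng.permutation(len(mets))]
    groups = {}
    start = 0
    for g, size in enumerate(sizes, start=1):
        groups[f"group{g}"] = frozenset(perm[start:start + size])
        start += size
    return GroupAssignment(groups=groups)


def detectability_curve(
    line_pairs: Sequence[tuple[PropagationResult, PropagationResult]],
) -> pd.DataFrame:
    """Ranking probability as a function of the true growth-rate difference.

    Takes already-propagated result pairs; returns one row per pair with the
    relative true difference (percent of the slower line's mu) and the
    probability of identifying the truly faster line, without smoothing.
    """
    rows = []
    for res_a, res_b in line_pairs:
        mu_a, mu_b = res_a.reference.mu_ref, res_b.reference.mu_ref
        summary = pairwise_ranking(res_a, res_b)
        rows.append({
            "mu_a": mu_a,
            "mu_b": mu_b,
            "delta_mu_pct": 100.0 * abs(mu_a - mu_b) / min(mu_a, mu_b),
            "p_correct": summary.p_correct,
            "n_pairs_compared": summary.n_pairs_compared,
        })
    return pd.DataFrame(rows).sort_values("delta_mu_pct", ignore_index=True)
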