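"""Small-world classification against the matched random ensemble.

Two criteria are implemented and compared:

* the **confidence-interval rule**: a web is small-world when its empirical
  CPL lies within or below the 99% percentile interval of the random CPL
  (CPL_emp <= CI upper bound, non-strict) *and* its empirical CC lies above
  the 99% interval of the random CC (CC_emp > CI upper bound, strict);

* the Humphries–Gurney **small-world-ness** index
  S^ws = (CC_emp / mean CC_rand) / (CPL_emp / mean CPL_rand) = gamma / lambda,
  declared small-world when S^ws > 1 and S^ws exceeds the 99.5% quantile of
  the null S^ws distribution.  The null distribution is built by scoring
  each random replicate against the ensemble means.

The ratios gamma = CC_emp / mean CC_rand and lambda = CPL_emp / mean
CPL_rand are also the coordinates used to position webs in the
(lambda, gamma) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import TopologySummary
from .null_ensemble import EnsembleSummary

__all__ = ["SWVerdict", "classify_conf", "small_world_ness", "evaluate", "compare_methods"]


@dataclass(frozen=True)
class SWVerdict:
    """Outcome of the small-world tests for one web."""

    name: str
    cpl_ratio: float  # lambda: CPL_emp / mean(CPL_rand)
    cc_ratio: float   # gamma:  CC_emp / mean(CC_rand)
    cpl_ok: bool | None = None
    cc_ok: bool | None = None
    is_small_world_conf: bool | None = None
    sws: float | None = None
    sws_ci_high: float | None = None
    is_small_world_sws: bool | None = None


def _check_matched(summary: TopologySummary, cpl_ens: EnsembleSummary, cc_ens: EnsembleSummary):
    if cpl_ens.S != cc_ens.S or cpl_ens.L != cc_ens.L:
        raise ValueError(
            f"CPL and CC ensembles disagree: ({cpl_ens.S},{cpl_ens.L}) vs ({cc_ens.S},{cc_ens.L})"
        )
    if cpl_ens.S != summary.S:
        raise ValueError(f"ensemble S={cpl_ens.S} does not match web S={summary.S}")
    if cpl_ens.L not in (summary.L, summary.E):
        raise ValueError(
            f"ensemble L={cpl_ens.L} matches neither directed links L={summary.L} "
            f"nor projection edges E={summary.E}"
        )


def _ratios(summary, cpl_ens, cc_ens) -> tuple[float, float]:
    if cpl_ens.mean <= 0 or cc_ens.mean <= 0:
        raise ValueError("ensemble mean must be positive to form empirical/random ratios")
    return summary.CPL / cpl_ens.mean, summary.CC / cc_ens.mean


def classify_conf(
    summary: TopologySummary,
    cpl_ens: EnsembleSummary,
    cc_ens: EnsembleSummary,
) -> SWVerdict:
    """Apply the confidence-interval small-world rule."""
    _check_matched(summary, cpl_ens, cc_ens)
    cpl_ratio, cc_ratio = _ratios(summary, cpl_ens, cc_ens)
    cpl_ok = summary.CPL <= cpl_ens.ci_high
    cc_ok = summary.CC > cc_ens.ci_high
    return SWVerdict(
        name=summary.name,
        cpl_ratio=cpl_ratio,
        cc_ratio=cc_ratio,
        cpl_ok=cpl_ok,
        cc_ok=cc_ok,
        is_small_world_conf=cpl_ok and cc_ok,
    )


def small_world_ness(
    summary: TopologySummary,
    cpl_ens: EnsembleSummary,
    cc_ens: EnsembleSummary,
) -> SWVerdict:
    """Compute S^ws and its null-quantile test.

    Requires aligned replicate vectors (replicate r of both ensembles from
    the same random graph), as produced by
    :func:`trophicsw.null_ensemble.ensemble_metrics`.
    """
    _check_matched(summary, cpl_ens, cc_ens)
    cpl_ratio, cc_ratio = _ratios(summary, cpl_ens, cc_ens)
    if len(cpl_ens.replicates) != len(cc_ens.replicates):
        raise ValueError("replicate vectors are not aligned")
    sws = cc_ratio / cpl_ratio
    null_sws = (cc_ens.replicates / cc_ens.mean) / (cpl_ens.replicates / cpl_ens.mean)
    alpha_high = 1.0 - (1.0 - cc_ens.level) / 2.0
    sws_ci_high = float(np.quantile(null_sws, alpha_high, method="linear"))
    return SWVerdict(
        name=summary.name,
        cpl_ratio=cpl_ratio,
        cc_ratio=cc_ratio,
        sws=sws,
        sws_ci_high=sws_ci_high,
        is_small_world_sws=(sws > 1.0) and (sws > sws_ci_high),
    )


def evaluate(
    summary: TopologySummary,
    cpl_ens: EnsembleSummary,
    cc_ens: EnsembleSummary,
) -> SWVerdict:
    """Run both small-world criteria and merge them into one verdict."""
    conf = classify_conf(summary, cpl_ens, cc_ens)
    sws = small_world_ness(summary, cpl_ens, cc_ens)
    return replace(
        conf,
        sws=sws.sws,
        sws_ci_high=sws.sws_ci_high,
        is_small_world_sws=sws.is_small_world_sws,
    )


def compare_methods(verdicts: list[SWVerdict]) -> dict:
    """Tally small-world calls under each criterion and list disagreements."""
    if not verdicts:
        raise ValueError("need at least one verdict")
    n_conf = sum(bool(v.is_small_world_conf) for v in verdicts)
    n_sws = sum(bool(v.is_small_world_sws) for v in verdicts)
    disagreements = [
        v.name for v in verdicts if bool(v.is_small_world_conf) != bool(v.is_small_world_sws)
    ]
    table = pd.DataFrame(
        {
            "name": [v.name for v in verdicts],
            "SW_conf": [bool(v.is_small_world_conf) for v in verdicts],
            "SW_sws": [bool(v.is_small_world_sws) for v in verdicts],
            "SWS": [v.sws for v in verdicts],
        }
    )
    return {
        "n_webs": len(verdicts),
        "n_sw_conf": n_conf,
        "n_sw_sws": n_sws,
        "disagreements": disagreements,
        "table": table,
    }
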