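"""Tabular reports tying extraction and inference together.

The ratio report carries, per site and dataset: the observed counts, the
discrete MAP ratio with its posterior probability (annotated when below
0.95), the full posterior, the copy-number-free 95% credible interval with
its separation classification against the two candidate proportions
bracketing the observed proportion, and — when several datasets are
analysed together — the strict-majority consensus ratio.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import VariableSite
from .observations import SiteObservation, observed_variant_proportion
from .ratios import (
    consensus_ratio,
    continuous_posterior,
    discrete_posterior,
    ratio_separation_check,
)

__all__ = ["ratio_report", "MISSING"]

MISSING = "."  # TSV missing-value marker

LOW_POSTERIOR = 0.95  # MAP probabilities below this are annotated


def _bracketing_candidates(p_hat: float, k: int) -> tuple[int, int]:
    """The two adjacent candidate js whose proportions bracket p_hat."""
    j_lo = int(np.clip(np.floor(p_hat * k), 1, k - 2))
    return j_lo + 1, j_lo


def ratio_report(
    datasets: Mapping[str, Sequence[SiteObservation]],
    sites: Sequence[VariableSite],
    k: int,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-site, per-dataset ratio estimates with consensus annotation."""
    if not datasets:
        raise ValueError("need at least one dataset")
    rows = []
    map_by_site: dict[int, list] = {i: [] for i in range(len(sites))}
    for name, observations in datasets.items():
        if len(observations) != len(sites):
            raise ValueError(
                f"dataset {name!r}: {len(observations)} observations for "
                f"{len(sites)} sites"
            )
        for i, (obs, site) in enumerate(zip(observations, sites)):
            row: dict = {"dataset": name, "position": site.position}
            try:
                x, n = observed_variant_proportion(obs, site)
            except ValueError:
                row.update(
                    x=MISSING, n=0, map_ratio=MISSING, map_probability=MISSING,
                    low_confidence=MISSING, posterior=MISSING,
                    ci_lower=MISSING, ci_upper=MISSING, separation=MISSING,
                )
                rows.append(row)
                continue
            rp = discrete_posterior(x, n, k)
            cp = continuous_posterior(x, n, level)
            j_hi, j_lo = _bracketing_candidates(x / n, k)
            map_by_site[i].append(rp.map_ratio)
            row.update(
                x=x,
                n=n,
                map_ratio=str(rp.map_ratio) if not rp.is_indeterminate else (
                    "|".join(
                        f"{max(j, k - j)}:{min(j, k - j)}" for j in rp.tied_js
                    )
                ),
                map_probability=round(rp.map_probability, 6),
                low_confidence=rp.map_probability < LOW_POSTERIOR
                or rp.is_indeterminate,
                posterior=json.dumps(
                    {str(j): round(p, 6) for j, p in zip(rp.candidates, rp.posterior)}
                ),
                ci_lower=round(cp.credible_interval[0], 6),
                ci_upper=round(cp.credible_interval[1], 6),
                separation=ratio_separation_check(cp, k, j_hi, j_lo),
            )
            rows.append(row)
    report = pd.DataFrame(rows)
    if len(datasets) > 1:
        consensus_by_pos = {}
        for i, site in enumerate(sites):
            estimates = map_by_site[i]
            if estimates:
                cons = consensus_ratio(estimates)
                consensus_by_pos[site.position] = (
                    str(cons) if cons is not None else "no-consensus"
                )
            else:
                consensus_by_pos[site.position] = MISSING
        report["consensus"] = report["position"].map(consensus_by_pos)
        report["agrees_with_consensus"] = [
            (row.map_ratio == row.consensus)
            if row.consensus not in (MISSING, "no-consensus")
            and row.map_ratio != MISSING
            else MISSING
            for row in report.itertuples()
        ]
    return report
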