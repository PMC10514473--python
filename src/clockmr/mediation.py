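"""Network-MR mediation: total, step-wise, and indirect effects.

The design decomposes the causal effect of an exposure on an outcome
through a candidate mediator in three independent IVW estimates:

    step a   exposure -> outcome   (theta_total; exposure instruments)
    step b   exposure -> mediator  (theta_b;     exposure instruments)
    step c   mediator -> outcome   (theta_c;     mediator instruments)

The indirect (mediator-borne) effect is the product theta_b * theta_c, with
a delta-method SE assuming independent step estimates (two-sample setting):

    se_indirect^2 = theta_b^2 se_c^2 + theta_c^2 se_b^2

and the mediated proportion is indirect / theta_total, again with a
delta-method SE.  A mediation result is reported as complete only when
instruments were available and the estimate succeeded at all three steps.
Step c is a one-to-one univariable IVW of the outcome on the mediator; the
mediator's instruments are drawn from the mediator GWAS with the same
selection thresholds as the exposure's, optionally restricted to a
user-supplied cis-region SNP list (for protein mediators, variants in or
near the encoding gene).

Proportions outside [0, 1] (inconsistent mediation, e.g. opposite-signed
direct and indirect paths) are reported as-is with a warning, never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import mr
from .gwas_io import harmonize, kept_pairs
from .instruments import select_instruments

logger = logging.getLogger(__name__)

Z95 = mr.Z95

DEFAULT_SELECTION = {
    "p_threshold": 5e-8,
    "clump_r2": 0.001,
    "clump_kb": 10_000,
    "maf_min": 0.01,
    "f_min": 10.0,
    "missing_ld": "retain",
}


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one candidate mediator."""

    mediator_id: str
    theta_total: float = np.nan
    se_total: float = np.nan
    theta_b: float = np.nan
    se_b: float = np.nan
    theta_c: float = np.nan
    se_c: float = np.nan
    indirect: float = np.nan
    se_indirect: float = np.nan
    proportion: float = np.nan
    se_proportion: float = np.nan
    proportion_ci_low: float = np.nan
    proportion_ci_high: float = np.nan
    screen_p_b: float = np.nan
    screen_p_c: float = np.nan
    n_snps_exposure: int = 0
    n_snps_mediator: int = 0
    complete: bool = False
    failed_steps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "mediator_id", "theta_total", "se_total", "theta_b", "se_b",
            "theta_c", "se_c", "indirect", "se_indirect", "proportion",
            "se_proportion", "proportion_ci_low", "proportion_ci_high",
            "screen_p_b", "screen_p_c", "n_snps_exposure", "n_snps_mediator",
            "complete",
        )}
        d["failed_steps"] = ",".join(self.failed_steps)
        return d


def _ivw_step(instruments: pd.DataFrame, target: pd.DataFrame,
              window: float, model: str) -> mr.MREstimate | None:
    try:
        pairs = kept_pairs(harmonize(instruments, target, palindrome_eaf_window=window))
        if len(pairs) < 2:
            return None
        return mr.ivw(pairs, model=model)
    except ValueError:
        return None


def run_mediation(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    selection: Mapping | None = None,
    palindrome_eaf_window: float = 0.08,
    mediator_cis_ids: Iterable[str] | None = None,
    model: str = "random",
    mediator_id: str = "mediator",
) -> MediationResult:
    """Run the three-step mediation analysis for one candidate mediator.

    ``selection`` overrides the instrument-selection thresholds (same keys
    as :func:`clockmr.instruments.select_instruments`); ``mediator_cis_ids``
    optionally restricts the mediator's instrument search to a cis-region
    SNP list.  Returns a :class:`MediationResult`; when any step lacks
    instruments or fails, the result is marked incomplete, the failing
    steps are named, and the indirect effect is withheld.
    """
    sel = dict(DEFAULT_SELECTION)
    if selection:
        sel.update(selection)

    res = MediationResult(mediator_id=mediator_id)

    exp_instr = select_instruments(exposure, **sel)
    res.n_snps_exposure = len(exp_instr)
    total = _ivw_step(exp_instr, outcome, palindrome_eaf_window, model) if len(exp_instr) >= 2 else None
    step_b = _ivw_step(exp_instr, mediator, palindrome_eaf_window, model) if len(exp_instr) >= 2 else None

    med_source = mediator
    if mediator_cis_ids is not None:
        cis = set(mediator_cis_ids)
        med_source = mediator[mediator["snp_id"].isin(cis)]
    med_instr = select_instruments(med_source, **sel) if len(med_source) else med_source
    res.n_snps_mediator = len(med_instr)
    step_c = _ivw_step(med_instr, outcome, palindrome_eaf_window, model) if len(med_instr) >= 2 else None

    if total is None:
        res.failed_steps.append("a_total")
    else:
        res.theta_total, res.se_total = total.theta, total.se
    if step_b is None:
        res.failed_steps.append("b_exposure_to_mediator")
    else:
        res.theta_b, res.se_b, res.screen_p_b = step_b.theta, step_b.se, step_b.pval
    if step_c is None:
        res.failed_steps.append("c_mediator_to_outcome")
    else:
        res.theta_c, res.se_c, res.screen_p_c = step_c.theta, step_c.se, step_c.pval

    if res.failed_steps:
        return res

    res.indirect = res.theta_b * res.theta_c
    res.se_indirect = float(
        np.sqrt(res.theta_b**2 * res.se_c**2 + res.theta_c**2 * res.se_b**2)
    )
    t = res.theta_total
    res.proportion = res.indirect / t
    var_prop = res.se_indirect**2 / t**2 + res.indirect**2 * res.se_total**2 / t**4
    res.se_proportion = float(np.sqrt(var_prop))
    res.proportion_ci_low = res.proportion - Z95 * res.se_proportion
    res.proportion_ci_high = res.proportion + Z95 * res.se_proportion
    res.complete = True
    if not 0.0 <= res.proportion <= 1.0:
        logger.warning(
            "mediator %s: mediated proportion %.3f outside [0, 1] (inconsistent mediation)",
            mediator_id, res.proportion,
        )
    return res


def screen_mediators(
    exposure: pd.DataFrame,
    mediators: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    alpha_screen: float = 0.05,
    selection: Mapping | None = None,
    palindrome_eaf_window: float = 0.08,
    mediator_cis_ids: Mapping[str, Iterable[str]] | None = None,
    model: str = "random",
) -> pd.DataFrame:
    """Screen many candidate mediators and rank the survivors.

    Step b (exposure -> mediator, exposure instruments) runs for every
    candidate; candidates with raw step-b p below ``alpha_screen`` proceed
    to step c and the full decomposition.  The output reports raw and
    Benjamini-Hochberg-adjusted step-b p-values for all candidates and is
    ranked with complete mediation results first, by descending |indirect|.
    An empty candidate set or an empty survivor set is a valid outcome.
    """
    sel = dict(DEFAULT_SELECTION)
    if selection:
        sel.update(selection)

    exp_instr = select_instruments(exposure, **sel)
    names = list(mediators)
    step_b: dict[str, mr.MREstimate | None] = {}
    for name in names:
        step_b[name] = (
            _ivw_step(exp_instr, mediators[name], palindrome_eaf_window, model)
            if len(exp_instr) >= 2
            else None
        )
    p_b = np.array([np.nan if step_b[n] is None else step_b[n].pval for n in names])
    p_bh = np.full_like(p_b, np.nan)
    ok = np.isfinite(p_b)
    if ok.any():
        p_bh[ok] = multipletests(p_b[ok], method="fdr_bh")[1]

    rows = []
    for i, name in enumerate(names):
        survived = bool(np.isfinite(p_b[i]) and p_b[i] < alpha_screen)
        if survived:
            cis = mediator_cis_ids.get(name) if mediator_cis_ids else None
            result = run_mediation(
                exposure, mediators[name], outcome,
                selection=sel, palindrome_eaf_window=palindrome_eaf_window,
                mediator_cis_ids=cis, model=model, mediator_id=name,
            )
        else:
            result = MediationResult(mediator_id=name)
            if step_b[name] is not None:
                result.theta_b = step_b[name].theta
                result.se_b = step_b[name].se
                result.screen_p_b = step_b[name].pval
        row = result.to_dict()
        row["screen_p_b_raw"] = p_b[i]
        row["screen_p_b_bh"] = p_bh[i]
        row["survived_screen"] = survived
        rows.append(row)

    out = pd.DataFrame(rows)
    if len(out):
        out["_rank_key"] = np.where(out["complete"], -np.abs(out["indirect"]), np.inf)
        out = out.sort_values(["_rank_key", "mediator_id"]).drop(columns="_rank_key")
        out = out.reset_index(drop=True)
    return out
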