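"""Per-channel mixed-effects contrasts of delta power between sleep states.

For each of the 14 bipolar channels a linear mixed-effects model relates the
per-subject, per-state median log delta power to sleep state (coded so that a
positive estimate means delta power is higher in quiet sleep), with sex and
postmenstrual age as fixed covariates and a random intercept per subject.  A
random-slope-for-state alternative is fit as well and the model with the
lower Bayesian information criterion is kept; both are fit by maximum
likelihood so the BICs are comparable across random-effects structures.
P-values are Wald tests on the state coefficient, corrected across channels
by the Benjamini–Hochberg step-up procedure at FDR 0.05.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .eeg import DEFAULT_BIPOLAR_PAIRS

__all__ = [
    "ChannelStatsRow", "MONTAGE_CHANNELS", "REFERENCE_CHANNEL_PVALUES",
    "bh_adjust", "fit_channel_lmm", "fit_all_channels", "significant_channels",
]

MONTAGE_CHANNELS: tuple[str, ...] = tuple(f"{a}-{c}" for a, c in DEFAULT_BIPOLAR_PAIRS)

#: Published per-channel raw p-values for the QS-vs-AS delta-power contrast on
#: this 14-channel montage, used as a reference input for validating the
#: multiple-comparison step (the underlying recordings are not public).
REFERENCE_CHANNEL_PVALUES: dict[str, float] = {
    "Fp1-T3": 0.023, "T3-O1": 0.035, "Fp2-T4": 0.929, "T4-O2": 0.627,
    "Fp1-C3": 0.319, "C3-O1": 0.261, "Fp2-C4": 0.047, "C4-O2": 0.017,
    "T3-C3": 0.019, "C3-Cz": 0.013, "Cz-C4": 0.017, "C4-T4": 0.471,
    "Fz-Cz": 0.001, "Cz-Pz": 0.005,
}


@dataclass
class ChannelStatsRow:
    """Mixed-model summary for one bipolar channel.

    ``estimate`` is the state coefficient in log-power units; positive means
    delta power is higher in QS than AS.
    """

    channel: str
    estimate: float
    p_value: float
    adj_p_value: float
    chosen_model: str               # "random_intercept" | "random_intercept_slope"
    bic_intercept: float
    bic_slope: float


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    Sort ascending, set ``q_(i) = p_(i) * m / i``, enforce monotonicity by a
    cumulative minimum from the largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def _prep(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["is_qs"] = (df["state"] == "QS").astype(float)
    if "sex" in df:
        df["sex_male"] = (df["sex"] == "M").astype(float)
    return df


def fit_channel_lmm(records: pd.DataFrame, channel: str,
                    include_sex: bool = True,
                    include_pma: bool = True) -> ChannelStatsRow:
    """Fit the QS-vs-AS mixed model for one channel and pick the lower-BIC fit.

    ``records`` needs columns subject_id, channel, state (AS/QS), delta_power,
    and (when the covariates are included) sex and pma_weeks.  Requires at
    least two subjects observed in both states on the channel.  The adjusted
    p-value is filled with NaN here; it is set across channels by
    :func:`fit_all_channels`.
    """
    df = _prep(records[records["channel"] == channel])
    both = df.groupby("subject_id")["is_qs"].nunique()
    if (both == 2).sum() < 2:
        raise ValueError(f"channel {channel}: need >= 2 subjects with both states")

    terms = ["is_qs"]
    if include_sex and "sex_male" in df:
        terms.append("sex_male")
    if include_pma and "pma_weeks" in df:
        terms.append("pma_weeks")
    formula = "delta_power ~ " + " + ".join(terms)

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            m = smf.mixedlm(formula, df, groups=df["subject_id"],
                            re_formula=re_formula)
            return m.fit(reml=False)

    try:
        fit_int = _fit("~1")
    except Exception as exc:   # singular / degenerate design
        raise ValueError(f"channel {channel}: singular random-intercept fit") from exc

    bic_int = float(fit_int.bic)
    try:
        fit_slope = _fit("~is_qs")
        bic_slope = float(fit_slope.bic)
        if not np.isfinite(bic_slope):
            raise RuntimeError("non-finite BIC")
    except Exception:
        fit_slope, bic_slope = None, float("nan")

    if fit_slope is not None and bic_slope < bic_int:
        chosen, name = fit_slope, "random_intercept_slope"
    else:
        chosen, name = fit_int, "random_intercept"

    est = float(chosen.params["is_qs"])
    p = float(chosen.pvalues["is_qs"])
    if not np.isfinite(p):
        raise ValueError(f"channel {channel}: degenerate fit (non-finite p-value)")
    return ChannelStatsRow(channel, est, p, float("nan"), name, bic_int, bic_slope)


def fit_all_channels(records: pd.DataFrame,
                     channels=MONTAGE_CHANNELS,
                     include_sex: bool = True,
                     include_pma: bool = True) -> pd.DataFrame:
    """Per-channel mixed models plus BH adjustment across channels.

    Returns one row per channel: channel, estimate, p_value, adj_p_value,
    chosen_model, bic_intercept, bic_slope.
    """
    rows = [fit_channel_lmm(records, ch, include_sex, include_pma)
            for ch in channels]
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["adj_p_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def significant_channels(rows: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int]:
    """Counts of channels significant before and after BH adjustment."""
    raw = int((rows["p_value"] < alpha).sum())
    adj = int((rows["adj_p_value"] < alpha).sum())
    return raw, adj
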