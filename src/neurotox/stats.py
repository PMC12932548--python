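"""Dose-response statistical layer.

Four pieces, mirroring how multi-well neurotoxicity assays are analysed:

* baseline normalization of time-course metrics (value at t divided by the
  pre-dose 0 h value of the same well/dose series),
* the group-comparison chain: Shapiro-Wilk normality per group, Bartlett's
  homogeneity across groups, one-way ANOVA, and Dunnett's many-to-one
  comparisons against the dose-0 control (two-sided, multivariate-t critical
  values computed numerically),
* classification of each (dose, timepoint) as excitatory / inhibitory /
  none from the normalized relative value, plus a per-dose trajectory label
  such as "inhibition->excitation",
* relative qPCR expression by the ddCt method, reported as -ddCt so that
  positive values mean enhanced expression.

With fewer than two replicates per group the formal tests are skipped and
descriptive relatives are all the pipeline reports — single-well MEA dose
groups cannot support inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "EffectCall",
    "normalize_to_baseline",
    "test_dose_groups",
    "classify_effects",
    "delta_delta_ct",
]


@dataclass
class StatResult:
    """ANOVA + Dunnett summary for one endpoint."""

    endpoint: str
    anova_F: float
    anova_p: float
    dunnett_p: dict[float, float]          # dose -> adjusted p vs control
    significant_05: dict[float, bool]
    significant_01: dict[float, bool]
    normality_p: dict[float, float]        # dose -> Shapiro-Wilk p
    homogeneity_p: float
    status: str = "ok"                     # ok | degenerate | skipped

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "dunnett_p": {str(k): v for k, v in self.dunnett_p.items()},
            "significant_05": {str(k): v for k, v in self.significant_05.items()},
            "significant_01": {str(k): v for k, v in self.significant_01.items()},
            "normality_p": {str(k): v for k, v in self.normality_p.items()},
            "homogeneity_p": self.homogeneity_p,
            "status": self.status,
        }


@dataclass(frozen=True)
class EffectCall:
    """Direction call for one (compound, dose, timepoint)."""

    compound: str
    dose: float
    timepoint: float
    relative: float
    direction: str  # excitatory | inhibitory | none


# --------------------------------------------------------------------------
# Baseline normalization
# --------------------------------------------------------------------------

def normalize_to_baseline(
    timeline: pd.DataFrame,
    value_col: str = "value",
    baseline_timepoint: float = 0.0,
    group_cols: tuple[str, ...] = ("compound", "dose", "metric"),
    timepoint_col: str = "timepoint",
) -> pd.DataFrame:
    """Divide each series by its pre-dose baseline value.

    Every ``group_cols`` series must contain a row at ``baseline_timepoint``.
    A zero baseline with a later zero value gives relative 0 (complete,
    sustained suppression); a zero baseline with a later non-zero value is
    undefined and returned as NaN with ``undefined=True``.
    """
    df = timeline.copy()
    out = []
    for key, grp in df.groupby(list(group_cols), sort=False):
        base_rows = grp[np.isclose(grp[timepoint_col], baseline_timepoint)]
        if base_rows.empty:
            raise ValueError(f"series {key} has no baseline ({baseline_timepoint}) row")
        base = float(base_rows[value_col].mean())
        g = grp.copy()
        if base != 0:
            g["relative"] = g[value_col] / base
            g["undefined"] = False
        else:
            vals = g[value_col].to_numpy(dtype=float)
            g["relative"] = np.where(vals == 0, 0.0, np.nan)
            g["undefined"] = vals != 0
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    n_undef = int(res["undefined"].sum())
    if n_undef:
        import logging

        logging.getLogger(__name__).warning(
            "normalize_to_baseline: %d values with zero baseline flagged undefined",
            n_undef,
        )
    return res


# --------------------------------------------------------------------------
# Group testing: Shapiro-Wilk / Bartlett / ANOVA / Dunnett
# --------------------------------------------------------------------------

def test_dose_groups(
    table: pd.DataFrame,
    value_col: str = "value",
    dose_col: str = "dose",
    endpoint_col: str = "endpoint",
    control_dose: float = 0.0,
    alpha: float = 0.05,
    rng: int | np.random.Generator | None = 0,
) -> list[StatResult]:
    """Run the normality / homogeneity / ANOVA / Dunnett chain per endpoint.

    Requires a control (dose-0) group and at least two groups with >= 2
    replicates each. Dunnett comparisons are two-sided against the control.
    Groups where every observation is identical make the chain degenerate;
    the result is returned with ``status='degenerate'`` and no significance
    claims.
    """
    results = []
    for endpoint, sub in table.groupby(endpoint_col, sort=False):
        doses = sorted(sub[dose_col].unique())
        if control_dose not in doses:
            raise ValueError(f"endpoint {endpoint!r}: no control group at dose {control_dose}")
        groups = {d: sub.loc[sub[dose_col] == d, value_col].to_numpy(float) for d in doses}
        if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
            raise ValueError(f"endpoint {endpoint!r}: need >=2 groups with >=2 replicates")
        treat_doses = [d for d in doses if d != control_dose]

        normality = {}
        for d, g in groups.items():
            if g.size >= 3 and np.ptp(g) > 0:
                normality[d] = float(sps.shapiro(g).pvalue)
            else:
                normality[d] = float("nan")

        degenerate = all(np.ptp(g) == 0 for g in groups.values()) or any(
            np.ptp(g) == 0 and g.size < 3 for g in groups.values()
        )
        pooled = np.concatenate(list(groups.values()))
        if degenerate or np.ptp(pooled) == 0:
            results.append(
                StatResult(
                    endpoint=str(endpoint),
                    anova_F=float("nan"), anova_p=float("nan"),
                    dunnett_p={d: float("nan") for d in treat_doses},
                    significant_05={d: False for d in treat_doses},
                    significant_01={d: False for d in treat_doses},
                    normality_p=normality, homogeneity_p=float("nan"),
                    status="degenerate",
                )
            )
            continue

        try:
            bart = float(sps.bartlett(*groups.values()).pvalue)
        except ValueError:
            bart = float("nan")
        F, p = sps.f_oneway(*groups.values())
        # the multivariate-t integration is randomized QMC; a fixed rng keeps
        # repeated runs byte-identical
        dun = sps.dunnett(
            *[groups[d] for d in treat_doses], control=groups[control_dose],
            alternative="two-sided", rng=rng,
        )
        dp = {d: float(pv) for d, pv in zip(treat_doses, dun.pvalue)}
        results.append(
            StatResult(
                endpoint=str(endpoint),
                anova_F=float(F), anova_p=float(p),
                dunnett_p=dp,
                significant_05={d: pv <= alpha for d, pv in dp.items()},
                significant_01={d: pv <= 0.01 for d, pv in dp.items()},
                normality_p=normality,
                homogeneity_p=bart,
            )
        )
    return results


# --------------------------------------------------------------------------
# Effect-direction classification
# --------------------------------------------------------------------------

_DIRECTION_WORD = {"excitatory": "excitation", "inhibitory": "inhibition",
                   "none": "none"}


def classify_effects(
    relative: pd.DataFrame,
    margin: float = 0.2,
    compound_col: str = "compound",
    dose_col: str = "dose",
    timepoint_col: str = "timepoint",
    relative_col: str = "relative",
) -> tuple[list[EffectCall], dict[tuple[str, float], str]]:
    """Call effect direction per (compound, dose, timepoint) and label the
    per-dose trajectory.

    A relative value above ``1 + margin`` is excitatory, below ``1 - margin``
    inhibitory, otherwise none. The trajectory joins the post-baseline calls
    in timepoint order, collapsing consecutive repeats (e.g. 0.4 then 1.6 ->
    "inhibition->excitation"). Undefined relatives (NaN) are skipped.
    """
    calls: list[EffectCall] = []
    trajectories: dict[tuple[str, float], str] = {}
    for (compound, dose), grp in relative.groupby(
        [compound_col, dose_col], sort=False
    ):
        grp = grp.sort_values(timepoint_col)
        words = []
        for _, row in grp.iterrows():
            tp = float(row[timepoint_col])
            rel = float(row[relative_col])
            if math.isnan(rel):
                continue
            if rel > 1 + margin:
                direction = "excitatory"
            elif rel < 1 - margin:
                direction = "inhibitory"
            else:
                direction = "none"
            calls.append(EffectCall(str(compound), float(dose), tp, rel, direction))
            if tp > 0:
                words.append(_DIRECTION_WORD[direction])
        collapsed = [w for i, w in enumerate(words) if i == 0 or w != words[i - 1]]
        trajectories[(str(compound), float(dose))] = (
            "→".join(collapsed) if collapsed else "none"
        )
    return calls, trajectories


# --------------------------------------------------------------------------
# ddCt
# --------------------------------------------------------------------------

def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str = "ACTB",
    calibrator: str | None = None,
    gene_col: str = "gene",
    condition_col: str = "condition",
    ct_col: str = "ct",
    extra_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Relative expression by the ddCt method, reported as -ddCt.

    Per (condition, *extra_cols*): dCt = mean Ct(target) - mean Ct(reference);
    ddCt = dCt(sample) - dCt(calibrator); the returned column is ``-ddCt``
    (positive = enhanced expression versus the calibrator; 2**(-ddCt) is the
    fold change). ``calibrator`` defaults to the first condition in the
    table. Any target/condition missing a reference Ct is rejected.
    """
    df = ct.copy()
    if calibrator is None:
        calibrator = df[condition_col].iloc[0]
    group_cols = [condition_col, *extra_cols]
    means = (
        df.groupby([*group_cols, gene_col])[ct_col].mean().reset_index()
    )
    ref = means[means[gene_col] == reference_gene].set_index(group_cols)[ct_col]
    targets = means[means[gene_col] != reference_gene]

    rows = []
    for _, row in targets.iterrows():
        key = tuple(row[c] for c in group_cols)
        key = key[0] if len(key) == 1 else key
        if key not in ref.index:
            raise ValueError(f"missing reference gene Ct for {key}")
        rows.append({
            condition_col: row[condition_col],
            **{c: row[c] for c in extra_cols},
            gene_col: row[gene_col],
            "delta_ct": row[ct_col] - float(ref.loc[key]),
        })
    dct = pd.DataFrame(rows)

    cal_mask = dct[condition_col] == calibrator
    cal_key_cols = [gene_col, *extra_cols] if extra_cols else [gene_col]
    cal = dct[cal_mask].set_index(cal_key_cols)["delta_ct"]
    out = dct.copy()
    cal_vals = []
    for _, row in out.iterrows():
        key = tuple(row[c] for c in cal_key_cols)
        key = key[0] if len(key) == 1 else key
        if key not in cal.index:
            raise ValueError(f"missing calibrator dCt for {key}")
        cal_vals.append(float(cal.loc[key]))
    out["delta_delta_ct"] = out["delta_ct"] - np.asarray(cal_vals)
    out["neg_delta_delta_ct"] = -out["delta_delta_ct"]
    out["fold_change"] = 2.0 ** out["neg_delta_delta_ct"]
    return out
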