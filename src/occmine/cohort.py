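"""Patient-level occupation profiles and missingness association models.

Text-mined patient-relation occupations are merged with the coded
occupational-status structured field into one profile per patient.  The
binary outcome *occupation recorded* — at least one occupation from either
source — is then modelled against sociodemographic and service-contact
predictors with standard maximum-likelihood logistic regression: a crude
model per predictor, a service-contact-adjusted model, and a fully adjusted
model, each with Wald 95% CIs per level and a likelihood-ratio test per
variable.

Two exclusions apply throughout, both deliberate: extractions labelled
``"other"`` (unnormalizable mentions, too imprecise to trust) and
healthcare-occupation labels (never credited to the patient) do not count
toward a patient's occupation record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .types import OTHER_LABEL, OccupationAnnotation, Relation

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ("age_band", "gender", "ethnicity", "marital",
                      "deprivation", "diagnosis", "events_quartile",
                      "bed_days")
SERVICE_VARS = ("events_quartile", "bed_days")


def build_profiles(
    annotations_by_patient: dict[str, list[OccupationAnnotation]],
    structured: pd.DataFrame,
    filter_labels: Iterable[str],
    patients: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One profile row per patient appearing in either source.

    ``extracted_labels`` holds the normalized patient-relation occupation
    labels, minus ``"other"`` and minus healthcare-filter labels;
    ``has_occupation`` is true when the structured status is present or the
    label set is non-empty.  Duplicate structured rows keep the first and
    warn.  ``patients`` (covariate table) rows are carried through when
    given, including patients with no occupation from either source.
    """
    filter_set = {lab.lower() for lab in filter_labels}
    dup = structured["patient_id"].duplicated()
    if dup.any():
        logger.warning("%d duplicate structured row(s); keeping first",
                       int(dup.sum()))
        structured = structured[~dup]
    status = structured.set_index("patient_id")["status_code"]

    ids: set[str] = set(status.index) | set(annotations_by_patient)
    if patients is not None:
        ids |= set(patients["patient_id"])

    rows = []
    for pid in sorted(ids):
        labels = sorted({
            a.label for a in annotations_by_patient.get(pid, [])
            if a.relation is Relation.PATIENT
            and a.label != OTHER_LABEL
            and a.label not in filter_set
        })
        structured_status = status.get(pid)
        rows.append({
            "patient_id": pid,
            "structured_status": (int(structured_status)
                                  if pd.notna(structured_status) else pd.NA),
            "extracted_labels": tuple(labels),
            "n_distinct": len(labels),
            "has_occupation": pd.notna(structured_status) or bool(labels),
        })
    profiles = pd.DataFrame(
        rows, columns=["patient_id", "structured_status", "extracted_labels",
                       "n_distinct", "has_occupation"])
    profiles["structured_status"] = profiles["structured_status"].astype("Int64")
    if patients is not None:
        profiles = profiles.merge(patients, on="patient_id", how="left")
    return profiles


def top_occupations(profiles: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Ranked table (label, n_patients, pct) counting each label once per
    patient; percentages are over *all* patients, not just those with an
    extraction.  Count ties break alphabetically."""
    n_total = len(profiles)
    counts: dict[str, int] = {}
    for labels in profiles["extracted_labels"]:
        for lab in set(labels):
            counts[lab] = counts.get(lab, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(
        [(lab, n, 100.0 * n / n_total if n_total else float("nan"))
         for lab, n in ranked],
        columns=["label", "n_patients", "pct"],
    )


@dataclass(frozen=True)
class DistinctCountSummary:
    """Distribution of distinct extracted occupation types per patient,
    among patients with at least one extraction.  Q1/Q3 and the
    interquartile width are all reported."""

    n: int
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    iqr_width: Optional[float]


def distinct_count_summary(profiles: pd.DataFrame) -> DistinctCountSummary:
    counts = profiles.loc[profiles["n_distinct"] > 0, "n_distinct"]
    if counts.empty:
        return DistinctCountSummary(n=0, median=None, q1=None, q3=None,
                                    iqr_width=None)
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    return DistinctCountSummary(n=len(counts), median=float(med),
                                q1=float(q1), q3=float(q3),
                                iqr_width=float(q3 - q1))


# ----------------------------------------------------------- associations

def _as_categorical(s: pd.Series) -> pd.Categorical:
    if isinstance(s.dtype, pd.CategoricalDtype):
        return pd.Categorical(s)
    return pd.Categorical(s, categories=sorted(pd.unique(s.dropna())))


def _fit_logit(formula: str, data: pd.DataFrame):
    try:
        model = smf.logit(formula, data=data)
        with np.errstate(all="ignore"):
            return model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError,
            ValueError):
        return None


def _lrt(full, data: pd.DataFrame, formula_reduced: str) -> Optional[float]:
    reduced = _fit_logit(formula_reduced, data)
    if full is None or reduced is None:
        return None
    stat = 2.0 * (full.llf - reduced.llf)
    df = full.df_model - reduced.df_model
    if df <= 0:
        return None
    return float(stats.chi2.sf(max(stat, 0.0), df))


def fit_association_models(
    profiles: pd.DataFrame,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    service_vars: tuple[str, ...] = SERVICE_VARS,
    outcome: str = "has_occupation",
) -> pd.DataFrame:
    """Crude, service-adjusted and fully adjusted logistic models.

    Returns a tidy frame with one row per predictor level per model:
    variable, level, n, pct_with_outcome, model, odds_ratio, ci_low,
    ci_high, lrt_p.  Reference levels carry OR = 1 with empty CIs.  Levels
    hit by perfect separation (or a failed fit) come back with null
    estimates and are flagged in the log.
    """
    predictors = tuple(p for p in predictors if p in profiles.columns)
    if not predictors:
        raise ValueError("no predictor columns present in profiles")
    data = profiles.copy()
    data["_y"] = data[outcome].astype(int)
    for var in predictors:
        data[var] = _as_categorical(data[var])
        if len(data[var].cat.categories) < 2:
            raise ValueError(f"predictor {var!r} has fewer than 2 levels")

    def term(var: str) -> str:
        return f"C({var})"

    all_terms = " + ".join(term(v) for v in predictors)
    rows = []
    for var in predictors:
        cats = list(data[var].cat.categories)
        adjusters = [v for v in service_vars if v in predictors and v != var]
        model_formulas = {
            "crude": (f"_y ~ {term(var)}", "_y ~ 1"),
            "service_adjusted": (
                f"_y ~ {term(var)}"
                + "".join(f" + {term(a)}" for a in adjusters),
                "_y ~ 1" + "".join(f" + {term(a)}" for a in adjusters)),
            "fully_adjusted": (
                f"_y ~ {all_terms}",
                " + ".join([f"_y ~ 1"]
                           + [term(v) for v in predictors if v != var])),
        }
        level_stats = data.groupby(var, observed=False)["_y"].agg(["count", "mean"])
        for model_name, (f_full, f_reduced) in model_formulas.items():
            fit = _fit_logit(f_full, data)
            if fit is None:
                logger.warning("fit failed for %s (%s)", var, model_name)
            lrt_p = _lrt(fit, data, f_reduced)
            for level in cats:
                n_level = int(level_stats.loc[level, "count"])
                pct = float(100.0 * level_stats.loc[level, "mean"])
                if level == cats[0]:
                    or_, lo, hi = 1.0, np.nan, np.nan
                elif fit is None:
                    or_, lo, hi = np.nan, np.nan, np.nan
                else:
                    pname = f"C({var})[T.{level}]"
                    if pname in fit.params.index:
                        beta = fit.params[pname]
                        se = fit.bse[pname]
                        if np.isfinite(beta) and np.isfinite(se) and se < 50:
                            or_ = float(np.exp(beta))
                            lo = float(np.exp(beta - 1.959964 * se))
                            hi = float(np.exp(beta + 1.959964 * se))
                        else:  # separation: unbounded estimate
                            or_, lo, hi = np.nan, np.nan, np.nan
                            logger.warning("separation flag: %s level %s",
                                           var, level)
                    else:
                        or_, lo, hi = np.nan, np.nan, np.nan
                rows.append({
                    "variable": var, "level": str(level), "n": n_level,
                    "pct_with_outcome": pct, "model": model_name,
                    "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                    "lrt_p": lrt_p,
                })
    return pd.DataFrame(rows)
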