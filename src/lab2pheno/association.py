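"""Phenotype-exposure association screen via logistic regression.

For each analyzable HPO term, a logistic model

    logit P(term present) = b0 + b1 * frequent_prednisone + b2 * acute_asthma

is fitted over patients whose status for the term is PRESENT or ABSENT
(INDETERMINATE patients are dropped per-term).  Coefficients are reported as
odds ratios exp(b) with confidence intervals exp(b +/- z * SE), z = 1.98 by
default, and two-sided Wald p-values (** for p < 0.01, * for p < 0.05).

Terms are excluded from the screen when the cohort is too uniform for the
model to be informative — when the majority share among PRESENT/ABSENT
patients reaches ``uniformity_threshold`` (default 95%) — or when fewer than
``min_term_patients`` patients carry the phenotype.  A Benjamini-Hochberg
q-value column is emitted for transparency but does not drive the
significance markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cohort import AnalysisConfig, PatientProfile, Presence
from .ontology import Ontology

__all__ = [
    "EXPOSURES",
    "Exposures",
    "ExposureEffect",
    "AssociationResult",
    "ScreenFailure",
    "ScreenReport",
    "filter_terms",
    "build_design",
    "fit_logistic",
    "LogisticFit",
    "run_screen",
    "odds_ratio_table",
    "write_report_tsv",
]

logger = logging.getLogger(__name__)

EXPOSURES = ("frequent_prednisone", "acute_asthma")


@dataclass(frozen=True)
class Exposures:
    frequent_prednisone: bool
    acute_asthma: bool


def significance_marker(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


@dataclass
class ExposureEffect:
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    significance: str
    bh_q: float | None = None


@dataclass
class AssociationResult:
    term: str
    label: str
    n_used: int
    n_present: int
    effects: dict[str, ExposureEffect]


@dataclass(frozen=True)
class ScreenFailure:
    term: str
    reason: str  # NON_CONVERGED | DEGENERATE
    detail: str = ""


@dataclass
class ScreenReport:
    results: list[AssociationResult]
    failures: list[ScreenFailure]
    excluded: dict[str, str]  # term -> exclusion reason


def _term_universe(profiles: Mapping[str, PatientProfile]) -> list[str]:
    terms: set[str] = set()
    for p in profiles.values():
        terms.update(p.propagated)
    return sorted(terms)


def filter_terms(
    profiles: Mapping[str, PatientProfile],
    cfg: AnalysisConfig = AnalysisConfig(),
    terms: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Split candidate terms into analyzable vs excluded (with reasons).

    A term is excluded when the majority share among its PRESENT/ABSENT
    patients is >= ``uniformity_threshold``, or when fewer than
    ``min_term_patients`` patients are PRESENT.
    """
    if terms is None:
        terms = _term_universe(profiles)
    analyzable: list[str] = []
    excluded: dict[str, str] = {}
    n_profiles = len(profiles)
    for term in terms:
        n_present = n_absent = 0
        for p in profiles.values():
            status = p.presence(term)
            if status is Presence.PRESENT:
                n_present += 1
            elif status is Presence.ABSENT:
                n_absent += 1
        total = n_present + n_absent
        if total == 0:
            excluded[term] = "NO_DETERMINATE_PATIENTS"
            continue
        if n_present < cfg.min_term_patients:
            excluded[term] = (
                f"TOO_FEW_PATIENTS ({n_present} < {cfg.min_term_patients})"
            )
            continue
        majority = max(n_present, n_absent) / total
        if majority >= cfg.uniformity_threshold:
            excluded[term] = (
                f"UNIFORM ({majority:.3f} >= {cfg.uniformity_threshold})"
            )
            continue
        analyzable.append(term)
    logger.info(
        "filter_terms: %d analyzable, %d excluded of %d candidates (%d profiles)",
        len(analyzable), len(excluded), len(terms), n_profiles,
    )
    return analyzable, excluded


def build_design(
    profiles: Mapping[str, PatientProfile],
    exposures: Mapping[str, Exposures],
    term: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (const + exposure indicators) and 0/1 outcome for a term.

    Only patients PRESENT (1) or ABSENT (0) for the term enter; patients
    missing exposure flags are skipped.
    """
    rows, y = [], []
    for pid in sorted(profiles):
        if pid not in exposures:
            continue
        status = profiles[pid].presence(term)
        if status is Presence.INDETERMINATE:
            continue
        e = exposures[pid]
        rows.append((pid, 1.0, float(e.frequent_prednisone), float(e.acute_asthma)))
        y.append(1.0 if status is Presence.PRESENT else 0.0)
    X = pd.DataFrame(
        [r[1:] for r in rows],
        columns=["const", *EXPOSURES],
        index=[r[0] for r in rows],
    )
    return X, pd.Series(y, index=X.index, name=term)


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    n_used: int


def fit_logistic(X: pd.DataFrame, y: pd.Series) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald standard errors/p-values.

    Separation or non-convergence yields ``converged=False`` (callers report
    a typed failure rather than aborting the screen).
    """
    if y.nunique() < 2:
        raise ValueError("outcome is constant")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
            converged = False
        # huge SEs are the practical signature of (quasi-)separation
        elif np.any(np.asarray(bse) > 50):
            converged = False
    except Exception as exc:  # PerfectSeparationError and numeric failures
        logger.warning("logistic fit failed: %s", exc)
        nan = pd.Series(np.nan, index=X.columns)
        return LogisticFit(nan, nan, nan, False, len(y))
    return LogisticFit(params, bse, pvalues, converged, len(y))


def _effects_from_fit(fit: LogisticFit, ci_z: float) -> dict[str, ExposureEffect]:
    effects = {}
    for name in fit.params.index:
        if name == "const":
            continue
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        p = float(fit.pvalues[name])
        effects[name] = ExposureEffect(
            beta=beta,
            se=se,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - ci_z * se)),
            ci_high=float(np.exp(beta + ci_z * se)),
            p=p,
            significance=significance_marker(p),
        )
    return effects


def run_screen(
    profiles: Mapping[str, PatientProfile],
    exposures: Mapping[str, Exposures],
    ont: Ontology | None = None,
    cfg: AnalysisConfig = AnalysisConfig(),
    terms: Sequence[str] | None = None,
) -> ScreenReport:
    """Fit the logistic model for every analyzable term.

    Deterministic given inputs; per-term failures are collected and the
    screen continues.  Benjamini-Hochberg q-values are attached per exposure
    across successfully fitted terms.
    """
    analyzable, excluded = filter_terms(profiles, cfg, terms)
    results: list[AssociationResult] = []
    failures: list[ScreenFailure] = []
    for term in analyzable:
        X, y = build_design(profiles, exposures, term)
        degenerate = [c for c in X.columns if c != "const" and X[c].nunique() < 2]
        if degenerate or y.nunique() < 2:
            failures.append(
                ScreenFailure(term, "DEGENERATE", f"constant columns: {degenerate}")
            )
            continue
        fit = fit_logistic(X, y)
        if not fit.converged:
            failures.append(ScreenFailure(term, "NON_CONVERGED"))
            continue
        results.append(
            AssociationResult(
                term=term,
                label=ont.label(term) if ont is not None else term,
                n_used=fit.n_used,
                n_present=int(y.sum()),
                effects=_effects_from_fit(fit, cfg.ci_z),
            )
        )
    for exposure in EXPOSURES:
        pvals = [r.effects[exposure].p for r in results]
        if pvals:
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for r, q in zip(results, qvals):
                r.effects[exposure].bh_q = float(q)
    return ScreenReport(results=results, failures=failures, excluded=excluded)


def odds_ratio_table(
    results: Sequence[AssociationResult],
    sort_by: str = "acute_asthma",
    or_gt_1: str | None = None,
) -> pd.DataFrame:
    """Report rows, sorted descending by the chosen exposure's odds ratio.

    ``or_gt_1`` optionally restricts rows to those with OR > 1 for that
    exposure, mirroring a filtered report view.
    """
    rows = []
    for r in results:
        row: dict[str, object] = {
            "hpo": r.term,
            "label": r.label,
            "n": r.n_used,
            "n_present": r.n_present,
        }
        for exposure, eff in r.effects.items():
            row[f"{exposure}_or"] = eff.odds_ratio
            row[f"{exposure}_ci"] = f"[{eff.ci_low:.2f}-{eff.ci_high:.2f}]"
            row[f"{exposure}_p"] = eff.p
            row[f"{exposure}_sig"] = eff.significance
            if eff.bh_q is not None:
                row[f"{exposure}_bh_q"] = eff.bh_q
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if or_gt_1 is not None:
        df = df[df[f"{or_gt_1}_or"] > 1.0]
    return df.sort_values(
        f"{sort_by}_or", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def write_report_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
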