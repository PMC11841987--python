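"""End-to-end orchestration: cohort -> scoring -> outcomes -> analyses.

The analysis battery mirrors a fear-conditioning study of childhood
adversity: manipulation checks (successful acquisition, a monotone
generalization gradient), the main exposed-vs-unexposed comparisons of CS
discrimination, LDS and general reactivity for SCRs and ratings (with a
2x2 mixed ANOVA and per-CS post-hoc tests when SCR discrimination differs),
exploratory operationalizations of exposure (severity groups, subscale
count, abuse/neglect composites separately and jointly with VIFs), a
theory comparison on a common |Cohen's d| scale, and the questionnaire
characterization table (group sizes, sex, age, STAI-T, ADS-K).

Group-difference tests switch from Student's to Welch's t when a
median-centred Levene pretest rejects variance homogeneity; exploratory
regressions switch to HC3 robust standard errors when a Breusch-Pagan
pretest rejects homoskedasticity. Post-hoc families are Holm-corrected;
the exploratory block is deliberately uncorrected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import het_breuschpagan
import statsmodels.api as sm

from . import stats as st
from .adversity import CutoffTable, classify
from .outcomes import build_outcome_set
from .scoring import ScoringConfig, score_recording, transform_amplitudes
from .synthetic import SimulationConfig, CohortDataset, generate_cohort

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "score_cohort",
    "run_manipulation_checks",
    "run_main_analysis",
    "run_exploratory_models",
    "run_theory_comparison",
    "run_questionnaire_analysis",
    "end_to_end",
]

OUTCOME_PHASE = {
    "cs_disc_acq": "ACQ", "cs_disc_gen": "GEN", "lds": "GEN", "reactivity": "ALL",
}
OUTCOME_ORDER = ("cs_disc_acq", "cs_disc_gen", "lds", "reactivity")
MEASURE_ORDER = ("scr", "arousal", "valence", "contingency")


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    cutoffs: CutoffTable = field(default_factory=CutoffTable)
    seed: int = 0
    scr_mode: str = "amplitude"  # "amplitude" | "signal"
    include_ratings: bool = True
    exclude_first: str = "per_cs"
    yuen_trim: float = 0.2
    out_dir: Path | None = None


@dataclass
class AnalysisReport:
    manipulation_checks: pd.DataFrame
    main: pd.DataFrame
    posthoc: pd.DataFrame
    exploratory: pd.DataFrame
    theory_comparison: pd.DataFrame
    questionnaire: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "manipulation_checks": self.manipulation_checks,
            "main_analysis": self.main,
            "posthoc": self.posthoc,
            "exploratory": self.exploratory,
            "theory_comparison": self.theory_comparison,
            "questionnaire": self.questionnaire,
        }


# --------------------------------------------------------------------------
# scoring stage
# --------------------------------------------------------------------------

def score_cohort(cohort: CohortDataset, scoring: ScoringConfig | None = None,
                 mode: str = "amplitude") -> pd.DataFrame:
    """Per-trial raw + transformed amplitude table for a simulated cohort.

    ``amplitude`` mode applies the minimum response criterion directly to
    the latent amplitudes; ``signal`` mode renders each participant's
    continuous recording and scores it through filtering + trough-to-peak.
    """
    scoring = scoring or ScoringConfig()
    if mode == "amplitude":
        table = cohort.amplitude_table(scoring)
    elif mode == "signal":
        parts = []
        for i in range(len(cohort.participants)):
            rec = cohort.render_recording(i)
            parts.append(score_recording(rec, cohort.schedule, scoring))
        table = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError(f"unknown scr mode {mode!r}")
    return transform_amplitudes(table, scoring)


# --------------------------------------------------------------------------
# analyses
# --------------------------------------------------------------------------

def _per_stim_means(table: pd.DataFrame, phase: str, value_col: str) -> pd.DataFrame:
    sel = table[table["phase"] == phase]
    return sel.groupby(["participant", "stimulus"], observed=True)[value_col].mean().unstack()


def _measure_tables(amplitudes: pd.DataFrame | None, ratings: pd.DataFrame | None):
    """(measure, trial-level table, value column) triples for all measures."""
    out = []
    if amplitudes is not None:
        out.append(("scr", amplitudes, "transformed"))
    if ratings is not None:
        from .outcomes import invert_valence

        if not ratings.loc[ratings["rating_type"] == "valence", "inverted"].all():
            ratings = invert_valence(ratings)
        for rtype in ("arousal", "valence", "contingency"):
            sel = ratings[ratings["rating_type"] == rtype]
            if not sel.empty:
                out.append((rtype, sel, "value"))
    return out


GRADIENT = ("CS+", "GS1", "GS2", "GS3", "GS4", "CS-")


def run_manipulation_checks(amplitudes: pd.DataFrame | None,
                            ratings: pd.DataFrame | None) -> pd.DataFrame:
    """Acquisition CS+ vs CS- and the five adjacent generalization-gradient
    steps per measure (paired t-tests, gradient family Holm-corrected)."""
    rows = []
    for measure, table, col in _measure_tables(amplitudes, ratings):
        acq = _per_stim_means(table, "acquisition", col)
        if {"CS+", "CS-"} <= set(acq.columns):
            res = st.paired_t(acq["CS+"], acq["CS-"])
            rows.append({"measure": measure, "check": "acquisition CS+ vs CS-",
                         "p_holm": res.p, **res.to_row()})
        gen = _per_stim_means(table, "generalization", col)
        missing = [s for s in GRADIENT if s not in gen.columns]
        if missing:
            rows.append({"measure": measure, "check": "generalization gradient",
                         "method": "skipped", "p_holm": np.nan,
                         "statistic": np.nan, "df": np.nan, "p": np.nan,
                         "effect_size": np.nan, "effect_label": f"missing {missing}",
                         "ci_lower": np.nan, "ci_upper": np.nan})
            continue
        fam = []
        for a, b in zip(GRADIENT[:-1], GRADIENT[1:]):
            res = st.paired_t(gen[a], gen[b])
            fam.append((f"generalization {a} vs {b}", res))
        adj = st.holm_correct([r.p for _, r in fam])
        for (label, res), ph in zip(fam, adj):
            rows.append({"measure": measure, "check": label, "p_holm": float(ph),
                         **res.to_row()})
    return pd.DataFrame(rows)


def _group_test(exposed_vals, unexposed_vals) -> st.GroupComparisonResult:
    """Student's t, or Welch's t when the Levene pretest rejects homogeneity.

    Statistic and d are oriented exposed minus unexposed, so attenuated
    responding in the exposed group yields negative values.
    """
    lev_p = st.levene_median(exposed_vals, unexposed_vals)
    if lev_p < st.ALPHA:
        res = st.welch_t(exposed_vals, unexposed_vals)
    else:
        res = st.student_t_ind(exposed_vals, unexposed_vals)
    res.extra["levene_p"] = lev_p
    return res


def run_main_analysis(outcomes: pd.DataFrame, exposed: pd.Series,
                      amplitudes: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main exposed-vs-unexposed table plus post-hoc rows.

    One row per outcome x measure. When the SCR CS-discrimination test of a
    phase is significant, a 2 (exposure) x 2 (CS type) mixed ANOVA on the
    per-participant CS means of that phase and Holm-corrected per-CS tests
    are appended to the post-hoc table.
    """
    exposed = exposed.astype(bool)
    if exposed.all() or (~exposed).all():
        raise ValueError("empty group: both exposed and unexposed participants required")
    rows, posthoc = [], []
    for measure in MEASURE_ORDER:
        block = outcomes[outcomes["measure"] == measure].set_index("participant")
        if block.empty:
            continue
        flags = exposed.reindex(block.index)
        for outcome in OUTCOME_ORDER:
            vals = block[outcome].dropna()
            f = flags.reindex(vals.index)
            if vals.empty or f.sum() < 2 or (~f).sum() < 2:
                continue
            res = _group_test(vals[f], vals[~f])
            rows.append({"outcome": outcome, "phase": OUTCOME_PHASE[outcome],
                         "measure": measure, **res.to_row()})
            if measure == "scr" and outcome.startswith("cs_disc") and res.significant \
                    and amplitudes is not None:
                phase = "acquisition" if outcome.endswith("acq") else "generalization"
                posthoc.extend(_scr_posthoc(amplitudes, exposed, phase))
    return pd.DataFrame(rows), pd.DataFrame(posthoc)


def _scr_posthoc(amplitudes: pd.DataFrame, exposed: pd.Series, phase: str) -> list[dict]:
    means = _per_stim_means(amplitudes, phase, "transformed")[["CS+", "CS-"]].dropna()
    flags = exposed.reindex(means.index).astype(bool)
    g1, g0 = means[flags], means[~flags]
    anova = st.mixed_anova_2x2(g1["CS+"], g1["CS-"], g0["CS+"], g0["CS-"])
    rows = [{"phase": phase, "contrast": f"mixed_anova:{k}", "p_holm": np.nan,
             **r.to_row()} for k, r in anova.items()]
    fam = [
        ("CS+ exposed vs unexposed", _group_test(g1["CS+"], g0["CS+"])),
        ("CS- exposed vs unexposed", _group_test(g1["CS-"], g0["CS-"])),
        ("CS+ vs CS- within exposed", st.paired_t(g1["CS+"], g1["CS-"])),
        ("CS+ vs CS- within unexposed", st.paired_t(g0["CS+"], g0["CS-"])),
    ]
    adj = st.holm_correct([r.p for _, r in fam])
    rows += [{"phase": phase, "contrast": c, "p_holm": float(ph), **r.to_row()}
             for (c, r), ph in zip(fam, adj)]
    return rows


def _regression_row(y: pd.Series, X: pd.DataFrame, model: str, outcome: str,
                    measure: str) -> list[dict]:
    """Per-coefficient rows for one exploratory regression (robust-SE switch
    via Breusch-Pagan)."""
    data = pd.concat([y.rename("__y"), X], axis=1).dropna()
    yv, Xv = data["__y"], data[X.columns]
    ols = sm.OLS(yv, sm.add_constant(Xv)).fit()
    bp_p = float(het_breuschpagan(ols.resid, sm.add_constant(Xv))[1])
    fit = st.ols_hc3(yv, Xv, robust=bp_p < st.ALPHA)
    out = []
    for col in X.columns:
        t = float(fit["t"][col])
        out.append({
            "model": model, "outcome": outcome, "measure": measure,
            "predictor": col, "coef": float(fit["params"][col]),
            "beta": fit["standardized_beta"][col], "t": t,
            "df_resid": fit["df_resid"], "p": float(fit["p"][col]),
            "r2": fit["r2"], "f": fit["f"], "df_model": fit["df_model"],
            "robust_se": fit["robust"], "n": int(len(yv)),
        })
    return out


def run_exploratory_models(outcomes: pd.DataFrame, classification: pd.DataFrame,
                           cutoffs: CutoffTable) -> pd.DataFrame:
    """Severity-group ANOVAs, subscale-count regressions, and the
    specificity / dimensional composite-score models (with VIFs)."""
    rows: list[dict] = []
    wide = outcomes.pivot_table(index="participant", columns="measure",
                                values=list(OUTCOME_ORDER), observed=True)
    cls = classification.reindex(wide.index)
    for measure in MEASURE_ORDER:
        for outcome in OUTCOME_ORDER:
            if (outcome, measure) not in wide.columns:
                continue
            y = wide[(outcome, measure)].dropna()
            if y.empty:
                continue
            c = cls.reindex(y.index)
            # (a) cumulative risk: severity groups
            if "severity_group" in c.columns:
                groups = [y[c["severity_group"] == g] for g in
                          c["severity_group"].cat.categories]
                groups = [g for g in groups if len(g) >= 2]
                if len(groups) >= 2:
                    res = st.one_way_anova(*groups)
                    rows.append({"model": "cumulative_risk_severity",
                                 "outcome": outcome, "measure": measure,
                                 **res.to_row(), "n": int(len(y))})
            # (b) cumulative risk: count of subscales above cut-off
            rows += _regression_row(y, c[["n_subscales_above"]].astype(float),
                                    "cumulative_risk_count", outcome, measure)
            # (c) specificity: separate abuse / neglect models
            for comp in ("abuse", "neglect"):
                rows += _regression_row(y, c[[comp]].astype(float),
                                        f"specificity_{comp}", outcome, measure)
            # (d) dimensional: joint, mutually adjusted, with VIFs
            X = c[["abuse", "neglect"]].astype(float)
            vifs = st.vif(X)
            for row in _regression_row(y, X, "dimensional", outcome, measure):
                row["vif"] = vifs[row["predictor"]]
                rows.append(row)
    return pd.DataFrame(rows)


def run_theory_comparison(main: pd.DataFrame, exploratory: pd.DataFrame,
                          outcome: str = "cs_disc_acq",
                          measure: str = "scr") -> pd.DataFrame:
    """Convert each exploratory effect for the chosen outcome to |Cohen's d|
    and compare it against the main-analysis CI for that outcome."""
    sel = main[(main["outcome"] == outcome) & (main["measure"] == measure)]
    if sel.empty:
        raise ValueError("main analysis row for the comparison outcome is missing")
    ci = (float(sel["ci_lower"].iloc[0]), float(sel["ci_upper"].iloc[0]))
    ex = exploratory[(exploratory["outcome"] == outcome)
                     & (exploratory["measure"] == measure)]
    rows = []
    for r in ex.itertuples():
        label = f"{r.model}" + (f":{r.predictor}" if hasattr(r, "predictor")
                                and isinstance(getattr(r, "predictor", None), str) else "")
        try:
            if r.model == "cumulative_risk_severity":
                dfs = [float(x) for x in str(r.df).split(",")]
                conv = st.effect_to_abs_d("f", r.statistic, df=dfs[1], df_num=dfs[0])
            else:
                conv = st.effect_to_abs_d("f", r.t**2, df=r.df_resid)
            d = conv["abs_d"]
            verdict = st.compare_to_main_ci({label: d}, ci)["verdicts"][label]
            rows.append({"theory": label, "abs_d": d, "conversion": conv["conversion"],
                         "verdict": verdict, "flag": ""})
        except ValueError as err:
            rows.append({"theory": label, "abs_d": np.nan, "conversion": "",
                         "verdict": "not_compared", "flag": str(err)})
    out = pd.DataFrame(rows)
    out.attrs["main_ci"] = ci
    out.attrs["any_outside"] = bool((out["verdict"] == "outside").any())
    return out


def run_questionnaire_analysis(participants: pd.DataFrame,
                               exposed: pd.Series) -> pd.DataFrame:
    """Sample-characterization table: N, sex, age, STAI-T, ADS-K by exposure."""
    exposed = exposed.astype(bool).reindex(participants.index)
    n_exp, n_un = int(exposed.sum()), int((~exposed).sum())
    if n_exp == 0 or n_un == 0:
        raise ValueError("empty group: both exposed and unexposed participants required")
    rows = []
    res = st.chi_square_gof([n_exp, n_un])
    rows.append({"variable": "N", "exposed": n_exp, "unexposed": n_un, **res.to_row()})
    if "female" in participants.columns:
        f = participants["female"].astype(bool)
        tab = [[int((f & exposed).sum()), int((~f & exposed).sum())],
               [int((f & ~exposed).sum()), int((~f & ~exposed).sum())]]
        res = st.chi_square_2x2(tab, correction=True)
        rows.append({"variable": "sex", "exposed": tab[0][0], "unexposed": tab[1][0],
                     **res.to_row()})
    for var, col in (("age", "age"), ("STAI-T", "stai_t"), ("ADS-K", "ads_k")):
        if col not in participants.columns:
            continue
        a, b = participants.loc[exposed, col], participants.loc[~exposed, col]
        res = st.welch_t(a, b)
        rows.append({"variable": var, "exposed": float(a.mean()),
                     "unexposed": float(b.mean()), **res.to_row()})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def end_to_end(config: AnalysisConfig) -> AnalysisReport:
    """Simulate, score, derive outcomes, classify, run every analysis block,
    and (optionally) serialize the report tables under ``config.out_dir``."""
    cohort = generate_cohort(config.simulation, seed=config.seed,
                             ratings=config.include_ratings)
    amplitudes = score_cohort(cohort, config.scoring, mode=config.scr_mode)
    ratings = cohort.ratings
    outcomes = build_outcome_set(amplitudes, ratings,
                                 exclude_first=config.exclude_first)
    parts = cohort.participants.set_index("participant")
    classification = classify(parts, config.cutoffs)

    checks = run_manipulation_checks(amplitudes, ratings)
    main, posthoc = run_main_analysis(outcomes, classification["exposed"], amplitudes)
    exploratory = run_exploratory_models(outcomes, classification, config.cutoffs)
    theory = run_theory_comparison(main, exploratory)
    quest = run_questionnaire_analysis(parts, classification["exposed"])

    cfg_repr = repr((config.simulation, config.scoring, config.cutoffs,
                     config.seed, config.scr_mode, config.include_ratings,
                     config.exclude_first, config.yuen_trim)).encode()
    provenance = {
        "seed": config.seed,
        "n": int(config.simulation.n),
        "scr_mode": config.scr_mode,
        "n_exposed": int(classification["exposed"].sum()),
        "config_sha1": hashlib.sha1(cfg_repr).hexdigest(),
    }
    report = AnalysisReport(checks, main, posthoc, exploratory, theory, quest,
                            provenance)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in report.tables().items():
            tab.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: AnalysisReport) -> str:
    lines = ["fear-conditioning adversity analysis", "=" * 38]
    p = report.provenance
    lines.append(f"seed={p['seed']} n={p['n']} exposed={p['n_exposed']} "
                 f"mode={p['scr_mode']}")
    lines.append("")
    lines.append("main analysis (exposed - unexposed):")
    for r in report.main.itertuples():
        lines.append(
            f"  {r.outcome:<12} {r.phase:<3} {r.measure:<11} "
            f"{r.method:<9} stat={r.statistic: .2f} p={r.p:.3f} "
            f"d={r.effect_size: .2f} CI[{r.ci_lower: .2f},{r.ci_upper: .2f}]"
        )
    lines.append("")
    tc = report.theory_comparison
    verdictline = ("no differential explanatory strength among theories"
                   if not tc.attrs.get("any_outside") else
                   "at least one theory differs from the main analysis")
    lines.append(f"theory comparison: {verdictline}")
    for r in tc.itertuples():
        lines.append(f"  {r.theory:<35} |d|={r.abs_d if np.isfinite(r.abs_d) else float('nan'):.3f} -> {r.verdict}")
    return "\n".join(lines) + "\n"
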