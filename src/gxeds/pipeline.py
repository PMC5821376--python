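"""Whole-study orchestration.

``run_analysis`` executes the full analysis for an :class:`AnalysisPlan`:
descriptive statistics, Hardy-Weinberg and linkage-disequilibrium checks,
haplotype estimation and moderator construction, gene-environment
correlation and sex checks, environment normality, main-effect and
interaction regressions per (outcome, moderator) pair, and — for
significant interactions — the nonlinearity check, the susceptibility
indices and the pattern label.  The resulting :class:`StudyReport`
renders to TSV (machine precision), JSON, and a rounded human-readable
table; identical inputs produce identical report bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import indices as dsi
from . import regression as reg
from .exceptions import GxedsError, SchemaError
from .genetics import (
    GenotypeTable,
    HaplotypeEstimate,
    SNPDef,
    assign_haplotype_moderator,
    assign_snp_moderator,
    em_haplotype_frequencies,
    hwe_test,
    ld_pairwise,
)

logger = logging.getLogger("gxeds")


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def cronbach_alpha(items: pd.DataFrame) -> float:
    """Internal consistency k/(k-1) * (1 - sum(item var) / var(total))."""
    if items.shape[1] < 2:
        raise ValueError("alpha requires at least two items")
    k = items.shape[1]
    item_var = items.var(ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1 - item_var / total_var))


def describe(
    phenotypes: pd.DataFrame,
    columns: Sequence[str] | None = None,
    item_scales: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-column mean, SD and observed range; Cronbach's alpha only for
    columns with an explicit item mapping (it is not computable from scale
    totals)."""
    cols = list(columns) if columns is not None else list(phenotypes.columns)
    rows = {}
    for col in cols:
        series = pd.to_numeric(phenotypes[col], errors="coerce")
        if series.isna().all():
            raise ValueError(f"column {col!r} is not numeric")
        alpha = float("nan")
        if item_scales and col in item_scales:
            alpha = cronbach_alpha(phenotypes[list(item_scales[col])])
        rows[col] = {
            "mean": series.mean(),
            "sd": series.std(ddof=1),
            "min": series.min(),
            "max": series.max(),
            "alpha": alpha,
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Plan
# ---------------------------------------------------------------------------

@dataclass
class AnalysisPlan:
    """What to analyse: outcomes, environment, moderators, covariates."""

    outcomes: list
    environment: str
    snps: list  # SNPDef
    moderators: list  # dicts: {"type": "snp", ...} / {"type": "haplotype", ...}
    covariates: list = field(default_factory=list)
    alpha: float = 0.05
    evaluation_range: Optional[tuple] = None
    higher_is_worse: bool = True
    compute_indices_always: bool = False
    em_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.outcomes:
            raise ValueError("plan needs at least one outcome")
        if not self.moderators:
            raise ValueError("plan needs at least one moderator")
        known = {s.rsid for s in self.snps}
        for spec in self.moderators:
            kind = spec.get("type")
            if kind == "snp":
                if spec["rsid"] not in known:
                    raise ValueError(f"moderator SNP {spec['rsid']} not declared")
            elif kind == "haplotype":
                for rsid in spec["rsids"]:
                    if rsid not in known:
                        raise ValueError(f"haplotype SNP {rsid} not declared")
            else:
                raise ValueError(f"unknown moderator type {kind!r}")
        if self.evaluation_range is not None:
            self.evaluation_range = tuple(self.evaluation_range)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "AnalysisPlan":
        kwargs = dict(mapping)
        kwargs["snps"] = [
            SNPDef(d["rsid"], d["non_risk_allele"], d["risk_allele"])
            for d in kwargs["snps"]
        ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown plan field(s): {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


REPORT_COLUMNS = [
    "outcome", "moderator", "n", "b0", "b1", "b2", "b3", "r2_adj",
    "p_x_main", "p_z_main", "p_interaction",
    "slope_z0", "slope_z0_p", "slope_z1", "slope_z1_ci_lower",
    "slope_z1_ci_upper", "slope_z1_p",
    "nonlinearity_p_joint", "nonlinearity_detected",
    "ros_lower", "ros_upper", "left_side_significant",
    "right_side_significant", "poi", "pa", "crossover", "pattern",
    "keller_interaction_p", "error",
]


@dataclass
class StudyReport:
    """Machine- and human-readable study results."""

    rows: pd.DataFrame
    descriptives: pd.DataFrame
    hwe: dict
    ld: pd.DataFrame
    haplotype: Optional[HaplotypeEstimate]
    ge_checks: dict
    sex_checks: dict
    normality: Optional[reg.NormalityTest]
    n_analysed: dict
    notes: list
    plan: AnalysisPlan

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        payload = {
            "rows": json.loads(self.rows.to_json(orient="records")),
            "descriptives": json.loads(self.descriptives.to_json(orient="index")),
            "hwe": {
                rsid: {
                    "observed": [int(v) for v in res.observed],
                    "chi2": res.chi2,
                    "p_value": res.p_value,
                    "monomorphic": res.monomorphic,
                }
                for rsid, res in self.hwe.items()
            },
            "ld": json.loads(self.ld.to_json(orient="records")),
            "haplotype_frequencies": (
                self.haplotype.frequencies if self.haplotype else None
            ),
            "ge_checks": {
                name: dataclasses.asdict(res) for name, res in self.ge_checks.items()
            },
            "sex_checks": self.sex_checks,
            "normality": (
                dataclasses.asdict(self.normality) if self.normality else None
            ),
            "n_analysed": self.n_analysed,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def render_text(self) -> str:
        """Rounded human-readable table (3 dp coefficients, 2 dp indices)."""
        disp = self.rows.copy()
        for col in ("b0", "b1", "b2", "b3", "crossover", "ros_lower", "ros_upper",
                    "slope_z0", "slope_z1", "slope_z1_ci_lower", "slope_z1_ci_upper"):
            disp[col] = disp[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.3f}"
            )
        for col in ("poi", "pa", "r2_adj"):
            disp[col] = disp[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        for col in ("p_interaction", "slope_z1_p", "keller_interaction_p"):
            disp[col] = disp[col].map(lambda v: "" if pd.isna(v) else f"{v:.3g}")
        keep = [
            "outcome", "moderator", "n", "b0", "b1", "b2", "b3", "r2_adj",
            "p_interaction", "slope_z1", "slope_z1_p", "ros_lower", "ros_upper",
            "poi", "pa", "crossover", "pattern",
        ]
        lines = [disp[keep].to_string(index=False)]
        if self.notes:
            lines += ["", *[f"note: {n}" for n in self.notes]]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _load_phenotypes(phenotypes) -> pd.DataFrame:
    if isinstance(phenotypes, pd.DataFrame):
        return phenotypes
    frame = pd.read_csv(phenotypes, sep=None, engine="python")
    if frame.empty or frame.shape[1] < 2:
        raise SchemaError(f"{phenotypes}: empty or malformed phenotype file")
    return frame.set_index(frame.columns[0])


def _moderator_name(spec: Mapping) -> str:
    if spec["type"] == "snp":
        return spec["rsid"]
    return spec.get("name", "HAPL")


def run_analysis(
    plan: AnalysisPlan,
    phenotypes,
    genotypes,
    outdir=None,
    make_plots: bool = False,
) -> StudyReport:
    """Execute the full study analysis and assemble the report.

    ``phenotypes``/``genotypes`` may be file paths or in-memory objects.
    Partial failures on a single (outcome, moderator) pair are logged and
    recorded in that row's ``error`` field rather than aborting the run.
    """
    phen = _load_phenotypes(phenotypes)
    if not isinstance(genotypes, GenotypeTable):
        genotypes = GenotypeTable.from_csv(genotypes, plan.snps)
    missing = [c for c in (*plan.outcomes, plan.environment, *plan.covariates)
               if c not in phen.columns]
    if missing:
        raise SchemaError(f"phenotype table lacks column(s): {missing}")
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)

    notes: list[str] = []
    descriptives = describe(phen, [*plan.outcomes, plan.environment])
    hwe = {rsid: hwe_test(genotypes.genotype_counts(rsid))
           for rsid in genotypes.rsids}

    # Haplotype estimation (once per distinct haplotype moderator block) and
    # LD from the marginalized joint frequencies.
    hap_est: HaplotypeEstimate | None = None
    hap_spec = next((s for s in plan.moderators if s["type"] == "haplotype"), None)
    ld_rows = []
    if hap_spec is not None:
        hap_est = em_haplotype_frequencies(
            genotypes, hap_spec["rsids"], n_restarts=plan.em_restarts,
            seed=plan.seed,
        )
        rsids = list(hap_spec["rsids"])
        for i in range(len(rsids)):
            for j in range(i + 1, len(rsids)):
                pairf = hap_est.marginal_pair_frequencies(rsids[i], rsids[j])
                ldstat = ld_pairwise(pairf)
                ld_rows.append(
                    {"rsid_a": rsids[i], "rsid_b": rsids[j],
                     "d_prime": ldstat.d_prime, "r_squared": ldstat.r_squared}
                )
    ld = pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "d_prime", "r_squared"])

    # Moderator groups.
    groups = {}
    for spec in plan.moderators:
        name = _moderator_name(spec)
        if spec["type"] == "snp":
            groups[name] = assign_snp_moderator(genotypes, spec["rsid"])
        else:
            groups[name] = assign_haplotype_moderator(
                hap_est,
                risk_haplotype=spec.get("risk", "CAT"),
                reference_haplotype=spec.get("reference", "AGC"),
                name=name,
            )

    # Dataset-level checks.
    env_series = pd.to_numeric(phen[plan.environment])
    ge_checks = {}
    for name, grp in groups.items():
        aligned = env_series.reindex(grp.coding.index).dropna()
        ge_checks[name] = reg.ge_correlation_check(
            aligned.to_numpy(), grp.coding.reindex(aligned.index).to_numpy()
        )
    sex_checks: dict = {}
    if "sex" in phen.columns:
        sex = pd.to_numeric(phen["sex"])
        for col in (plan.environment, *plan.outcomes):
            vals = pd.to_numeric(phen[col])
            res = reg.ge_correlation_check(vals.to_numpy(), sex.to_numpy())
            sex_checks[col] = {"t": res.t_stat, "p": res.p_value, "d": res.cohens_d}
    normality = None
    env_clean = env_series.dropna()
    if 3 <= len(env_clean) <= 5000:
        normality = reg.normality_check(env_clean.to_numpy())
    else:
        notes.append("environment normality check skipped (n out of range)")

    polarity = dsi.OutcomePolarity(higher_is_worse=plan.higher_is_worse)
    rows = []
    n_analysed = {}
    any_significant = False
    for name, grp in groups.items():
        for outcome in plan.outcomes:
            row = {c: np.nan for c in REPORT_COLUMNS}
            row.update(outcome=outcome, moderator=name, pattern="", error="")
            try:
                data = reg.AnalysisDataset.assemble(
                    phen, outcome, plan.environment, grp, plan.covariates
                )
                n_analysed[f"{outcome}|{name}"] = len(data)
                # Main-effect models fitted separately, as in the study design.
                xmat = sm.add_constant(data.x)
                row["p_x_main"] = float(sm.OLS(data.y, xmat).fit().pvalues[1])
                zmat = sm.add_constant(data.z)
                row["p_z_main"] = float(sm.OLS(data.y, zmat).fit().pvalues[1])

                fit = reg.fit_gxe(data)
                b0, b1, b2, b3 = fit.b
                s0, s1 = fit.simple_slopes(alpha=plan.alpha)
                row.update(
                    n=len(data), b0=b0, b1=b1, b2=b2, b3=b3,
                    r2_adj=fit.rsquared_adj,
                    p_interaction=fit.interaction_pvalue,
                    slope_z0=s0.estimate, slope_z0_p=s0.p_value,
                    slope_z1=s1.estimate, slope_z1_ci_lower=s1.ci_lower,
                    slope_z1_ci_upper=s1.ci_upper, slope_z1_p=s1.p_value,
                )
                significant = fit.interaction_pvalue < plan.alpha
                if significant or plan.compute_indices_always:
                    any_significant = any_significant or significant
                    nl = reg.fit_nonlinear_check(data).nonlinearity_check(
                        alpha=plan.alpha
                    )
                    row["nonlinearity_p_joint"] = nl.p_joint
                    row["nonlinearity_detected"] = nl.detected
                    env = dsi.EnvironmentSummary.from_sample(
                        data.x, range_override=plan.evaluation_range
                    )
                    idx = dsi.compute_indices(fit, env, polarity, alpha=plan.alpha)
                    row.update(
                        ros_lower=idx.ros_lower, ros_upper=idx.ros_upper,
                        left_side_significant=idx.left_side_significant,
                        right_side_significant=idx.right_side_significant,
                        poi=idx.poi, pa=idx.pa, crossover=idx.crossover,
                        pattern=idx.pattern,
                    )
                    if make_plots and outdir is not None:
                        fig_path = Path(outdir) / f"interaction_{outcome}_{name}.png"
                        dsi.plot_interaction(fit, env, idx, path=fig_path)
                else:
                    row["pattern"] = "no_interaction"
                if plan.covariates:
                    keller = reg.fit_keller_adjusted(data)
                    row["keller_interaction_p"] = keller.interaction_pvalue
            except (GxedsError, ValueError, KeyError) as exc:
                logger.warning("skipping %s x %s: %s", outcome, name, exc)
                row["error"] = str(exc)
            rows.append(row)
    if not any_significant and not plan.compute_indices_always:
        notes.append(
            "no significant GxE interactions at alpha="
            f"{plan.alpha}; susceptibility indices not computed"
        )

    report = StudyReport(
        rows=pd.DataFrame(rows, columns=REPORT_COLUMNS),
        descriptives=descriptives,
        hwe=hwe,
        ld=ld,
        haplotype=hap_est,
        ge_checks=ge_checks,
        sex_checks=sex_checks,
        normality=normality,
        n_analysed=n_analysed,
        notes=notes,
        plan=plan,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_tsv(outdir / "report.tsv")
        report.to_json(outdir / "report.json")
        (outdir / "report.txt").write_text(report.render_text() + "\n")
    return report
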