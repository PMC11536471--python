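"""Cohort-level summaries: per-gene growth, co-occurrence, covariate models.

Gene summaries are plain arithmetic means of per-clone growth rates;
genes below a minimum clone count are reported but flagged as under-
powered.  The driver-gene co-occurrence test asks whether the gene
pairs found in two-mutation individuals depart from what the marginal
driver-gene prevalences predict: under the null, an individual's two
genes are independent draws from the prevalence distribution, so the
expected count of the unordered pair {g, h} among n individuals is
n * 2 * p_g * p_h (g != h) or n * p_g^2 (g == h).  Both an analytic
chi-square p-value and a permutation p-value are available — expected
cells are tiny at realistic n, where the asymptotic chi-square is
unreliable.

Covariate associations are least-squares models of clone growth rate
on one covariate at a time with driver-gene fixed effects, one row per
clone (optionally the fastest clone per individual).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonal_dynamics import (
    EXPANSION,
    REDUCTION,
    STAGNANT,
    TrajectoryAssignment,
)

logger = logging.getLogger("chipdyn")


# ---------------------------------------------------------------------------
# Per-gene growth summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSummary:
    gene: str
    n_clones: int
    mean_cf: float
    sd_cf: float
    n_expansion: int
    n_reduction: int
    n_stagnant: int
    mean_reduction_rate: float | None
    below_threshold: bool


def summarize_by_gene(
    assignments: Sequence[TrajectoryAssignment],
    min_n: int = 10,
) -> list[GeneSummary]:
    """Per-gene mean growth rate and trajectory-class counts.

    Every gene present is reported; genes with fewer than ``min_n``
    clones are flagged ``below_threshold`` and should be excluded from
    rankings.  ``mean_reduction_rate`` is the mean CF among that gene's
    reduction-class clones (None when there are none).
    """
    by_gene: dict[str, list[TrajectoryAssignment]] = {}
    for a in assignments:
        by_gene.setdefault(a.clone.gene, []).append(a)
    summaries = []
    for gene in sorted(by_gene):
        members = by_gene[gene]
        cfs = np.array([m.cf for m in members], dtype=float)
        reductions = [m.cf for m in members if m.trajectory == REDUCTION]
        summaries.append(GeneSummary(
            gene=gene,
            n_clones=len(members),
            mean_cf=float(cfs.mean()),
            sd_cf=float(np.std(cfs, ddof=1)) if len(cfs) > 1 else 0.0,
            n_expansion=sum(m.trajectory == EXPANSION for m in members),
            n_reduction=sum(m.trajectory == REDUCTION for m in members),
            n_stagnant=sum(m.trajectory == STAGNANT for m in members),
            mean_reduction_rate=float(np.mean(reductions)) if reductions else None,
            below_threshold=len(members) < min_n,
        ))
    return summaries


def sensitivity_single_mutation(
    assignments: Sequence[TrajectoryAssignment],
    min_n: int = 10,
) -> tuple[list[GeneSummary], float]:
    """Gene summaries restricted to individuals with exactly one mutation.

    Guards against multi-clone individuals skewing gene means.  Returns
    the restricted summaries and the fraction of clones removed.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.clone.individual_id] = counts.get(a.clone.individual_id, 0) + 1
    restricted = [a for a in assignments if counts[a.clone.individual_id] == 1]
    removed = 1 - len(restricted) / len(assignments) if assignments else 0.0
    logger.info(
        "single-mutation sensitivity: %d/%d clones kept (%.0f%% removed)",
        len(restricted), len(assignments), 100 * removed,
    )
    return summarize_by_gene(restricted, min_n=min_n), removed


def gene_summaries_to_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    cols = ["gene", "n_clones", "mean_cf", "sd_cf", "n_expansion",
            "n_reduction", "n_stagnant", "mean_reduction_rate", "below_threshold"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries], columns=cols)


# ---------------------------------------------------------------------------
# Driver-gene co-occurrence
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceResult:
    observed: dict[tuple[str, str], int]
    expected: dict[tuple[str, str], float]
    chi2: float
    p_analytic: float | None
    p_permutation: float | None
    n_pairs: int
    df: int


def _pair_key(g: str, h: str) -> tuple[str, str]:
    return tuple(sorted((g, h)))  # type: ignore[return-value]


def _chi2_statistic(
    observed: Mapping[tuple[str, str], int],
    expected: Mapping[tuple[str, str], float],
) -> float:
    return float(sum(
        (observed.get(cell, 0) - e) ** 2 / e
        for cell, e in expected.items()
        if e > 0
    ))


def expected_pair_counts(
    gene_prevalence: Mapping[str, float],
    n_pairs: int,
) -> dict[tuple[str, str], float]:
    """Expected unordered-pair counts under independent prevalence draws."""
    total = sum(gene_prevalence.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"gene prevalences must sum to 1 (got {total})")
    genes = sorted(g for g, p in gene_prevalence.items() if p > 0)
    expected = {}
    for g, h in itertools.combinations_with_replacement(genes, 2):
        p_g, p_h = gene_prevalence[g], gene_prevalence[h]
        expected[(g, h)] = n_pairs * (p_g * p_h if g == h else 2 * p_g * p_h)
    return expected


def cooccurrence_test(
    gene_pairs: Sequence[tuple[str, str]],
    gene_prevalence: Mapping[str, float],
    method: str = "both",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> CooccurrenceResult:
    """Test observed driver-gene pairings against the prevalence null.

    ``gene_pairs`` has one unordered gene pair per two-mutation
    individual (same-gene pairs are legal).  ``gene_prevalence`` is the
    marginal gene frequency among all retained mutations.  The analytic
    p uses the chi-square distribution with (#cells - 1) degrees of
    freedom (prevalences are treated as known, not estimated from the
    pairs); the permutation p resamples pairs from the prevalence
    distribution and is the honest choice when expected cells are < 5.
    """
    if not gene_pairs:
        raise ValueError("no gene pairs: co-occurrence test undefined")
    if method not in ("analytic", "permutation", "both"):
        raise ValueError(f"unknown method {method!r}")
    n_pairs = len(gene_pairs)
    observed: dict[tuple[str, str], int] = {}
    for g, h in gene_pairs:
        key = _pair_key(g, h)
        if key[0] not in gene_prevalence or key[1] not in gene_prevalence:
            raise ValueError(f"pair {key} contains a gene absent from prevalence")
        observed[key] = observed.get(key, 0) + 1
    expected = expected_pair_counts(gene_prevalence, n_pairs)
    chi2 = _chi2_statistic(observed, expected)
    n_cells = sum(1 for e in expected.values() if e > 0)
    df = max(n_cells - 1, 1)

    p_analytic = None
    if method in ("analytic", "both"):
        p_analytic = float(stats.chi2.sf(chi2, df))

    p_permutation = None
    if method in ("permutation", "both"):
        if seed is None:
            raise ValueError("permutation method requires a seed")
        rng = np.random.default_rng(seed)
        genes = sorted(g for g, p in gene_prevalence.items() if p > 0)
        probs = np.array([gene_prevalence[g] for g in genes])
        probs = probs / probs.sum()
        draws = rng.choice(len(genes), size=(n_perm, n_pairs, 2), p=probs)
        exceed = 0
        for rep in range(n_perm):
            obs_rep: dict[tuple[str, str], int] = {}
            for i, j in draws[rep]:
                key = _pair_key(genes[i], genes[j])
                obs_rep[key] = obs_rep.get(key, 0) + 1
            if _chi2_statistic(obs_rep, expected) >= chi2:
                exceed += 1
        p_permutation = (1 + exceed) / (n_perm + 1)

    return CooccurrenceResult(
        observed=observed, expected=expected, chi2=chi2,
        p_analytic=p_analytic, p_permutation=p_permutation,
        n_pairs=n_pairs, df=df,
    )


def gene_prevalence_from_assignments(
    assignments: Sequence[TrajectoryAssignment],
) -> dict[str, float]:
    """Marginal driver-gene frequencies among all retained mutations."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.clone.gene] = counts.get(a.clone.gene, 0) + 1
    total = sum(counts.values())
    return {g: c / total for g, c in sorted(counts.items())}


def gene_pairs_from_assignments(
    assignments: Sequence[TrajectoryAssignment],
) -> list[tuple[str, str]]:
    """One unordered gene pair per two-mutation individual."""
    by_individual: dict[str, list[str]] = {}
    for a in assignments:
        by_individual.setdefault(a.clone.individual_id, []).append(a.clone.gene)
    return [
        _pair_key(*genes)
        for _, genes in sorted(by_individual.items())
        if len(genes) == 2
    ]


# ---------------------------------------------------------------------------
# Covariate associations
# ---------------------------------------------------------------------------

def associate_covariates(
    assignments: Sequence[TrajectoryAssignment],
    metadata: pd.DataFrame,
    covariates: Sequence[str],
    fastest_only: bool = False,
) -> pd.DataFrame:
    """Test each covariate against clone growth rate, gene-adjusted.

    Fits, per covariate, the least-squares model

        cf ~ covariate + C(gene)

    with one row per clone (or per individual's fastest clone when
    ``fastest_only``).  When individuals contribute several clones,
    standard errors are cluster-robust by individual — covariates are
    individual-level and nested sub-clones have correlated growth, so
    i.i.d. errors would understate uncertainty.  Categorical covariates
    enter as dummy terms and are summarised by their joint Wald test.
    Covariates with zero variance are skipped with a warning; covariates
    collinear with the gene labels are reported with
    ``flag='collinear'`` rather than silently dropped.

    Returns a tidy frame: covariate, coef, se, p, n, flag.
    """
    import statsmodels.formula.api as smf

    meta = metadata.drop_duplicates("individual_id").set_index("individual_id")
    rows = []
    for a in assignments:
        iid = a.clone.individual_id
        if iid not in meta.index:
            continue
        row = {"individual_id": iid, "cf": a.cf, "gene": a.clone.gene}
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no clones join to the metadata")
    if fastest_only:
        frame = frame.loc[frame.groupby("individual_id")["cf"].idxmax()]
    frame = frame.join(meta, on="individual_id")

    results = []
    for cov in covariates:
        if cov not in frame.columns:
            results.append({"covariate": cov, "coef": np.nan, "se": np.nan,
                            "p": np.nan, "n": 0, "flag": "missing"})
            continue
        sub = frame.dropna(subset=[cov, "cf"])
        if sub[cov].nunique() < 2:
            logger.warning("covariate %s has zero variance; skipped", cov)
            results.append({"covariate": cov, "coef": np.nan, "se": np.nan,
                            "p": np.nan, "n": len(sub), "flag": "zero_variance"})
            continue
        numeric = pd.api.types.is_numeric_dtype(sub[cov])
        term = cov if numeric else f"C({cov})"
        multi_gene = sub["gene"].nunique() > 1
        formula = f"cf ~ {term}" + (" + C(gene)" if multi_gene else "")
        # collinearity with gene labels: covariate fully explained by gene
        flag = ""
        if multi_gene:
            x = sub[cov] if numeric else pd.factorize(sub[cov])[0]
            gene_dummies = pd.get_dummies(sub["gene"], drop_first=False).to_numpy(float)
            xv = np.asarray(x, dtype=float)
            resid = xv - gene_dummies @ np.linalg.lstsq(gene_dummies, xv, rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-10 * max(1.0, np.abs(xv).max())):
                flag = "collinear"
        model = smf.ols(formula, data=sub)
        clustered = sub["individual_id"].duplicated().any()
        if clustered:
            fit = model.fit(
                cov_type="cluster",
                cov_kwds={"groups": sub["individual_id"]},
                use_t=True,
            )
        else:
            fit = model.fit()
        cov_terms = [t for t in fit.params.index
                     if t == cov or t.startswith(f"C({cov})")]
        if numeric:
            coef = float(fit.params[cov])
            se = float(fit.bse[cov])
            p = float(fit.pvalues[cov])
        else:
            wald = fit.wald_test(
                [t for t in cov_terms], scalar=True, use_f=True
            )
            coef = float(fit.params[cov_terms[0]])
            se = float(fit.bse[cov_terms[0]])
            p = float(wald.pvalue)
        if flag == "collinear" or not np.isfinite(se):
            flag = flag or "collinear"
            logger.warning("covariate %s is collinear with driver-gene labels", cov)
        results.append({"covariate": cov, "coef": coef, "se": se, "p": p,
                        "n": int(fit.nobs), "flag": flag})
    return pd.DataFrame(results, columns=["covariate", "coef", "se", "p", "n", "flag"])


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_growth_by_gene(assignments, path, min_n: int = 10):
    """Strip plot of per-clone growth rates by driver gene."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pd.DataFrame({
        "gene": [a.clone.gene for a in assignments],
        "cf": [a.cf for a in assignments],
    })
    order = (frame.groupby("gene")["cf"].mean().sort_values(ascending=False).index)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(order) + 1.5))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, gene in enumerate(order):
        vals = frame.loc[frame.gene == gene, "cf"]
        ax.scatter(vals, i + rng.uniform(-0.15, 0.15, len(vals)), s=12, alpha=0.6)
        ax.scatter([vals.mean()], [i], s=60, marker="D", color="black", zorder=3)
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel("annual growth rate (CF)")
    ax.set_xlim(right=min(1.2, max(frame.cf.max(), 0.2)))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_vaf_trajectories(assignments, path):
    """VAF-over-time line plot, one line per clone, coloured by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {STAGNANT: "#888888", EXPANSION: "#c0392b", REDUCTION: "#2980b9"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for a in assignments:
        p = a.clone
        ax.plot([0, p.dt_years], [p.vaf1, p.vaf2],
                color=colors.get(a.trajectory, "black"), alpha=0.5, lw=1)
    ax.set_xlabel("years between draws")
    ax.set_ylabel("VAF")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
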