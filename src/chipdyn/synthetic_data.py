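"""Ground-truthed synthetic two-timepoint CHIP cohorts.

Real longitudinal biobank data behind this kind of analysis is access-
restricted, so the generator emulates the statistical structure the
pipeline assumes and every stage is testable against known truth:

* per-individual driver-mutation counts (defaults 66% one, 26% two,
  8% three or more);
* a skewed driver-gene distribution dominated by DNMT3A and TET2;
* deterministic exponential clone growth with gene-specific annual
  rates (e.g. DNMT3A ~8%/yr, JAK2 ~109%/yr), clone VAF = cell
  fraction / 2 for heterozygous autosomal mutations;
* two-clone architectures: distinct clones (independent cell
  populations, total fraction capped at 1) or nested sub-clones (the
  child mutation rides inside the parent clone, its cell fraction
  capped at the parent's, its growth rate the parent's plus a small
  increment);
* sequencing noise: depth ~ Poisson(mean depth, default 1725x),
  alt reads ~ Binomial(depth, true VAF).

Everything is driven by one seeded generator: the same config and seed
give byte-identical fixtures.  Growth is deterministic exponential
plus sampling noise — no stem-cell population dynamics (drift,
competition) are simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel_and_variants import PanelDefinition, load_panel

logger = logging.getLogger("chipdyn")

#: Driver-gene frequencies among mutations (skewed toward DNMT3A/TET2).
DEFAULT_GENE_FREQUENCIES: dict[str, float] = {
    "DNMT3A": 0.50, "TET2": 0.17, "JAK2": 0.09, "PPM1D": 0.07,
    "ASXL1": 0.06, "SF3B1": 0.03, "SRSF2": 0.025, "TP53": 0.02,
    "GNAS": 0.015, "KRAS": 0.01, "IDH2": 0.01,
}

#: (mean annual growth rate, between-clone SD) per driver gene.
DEFAULT_GENE_GROWTH: dict[str, tuple[float, float]] = {
    "DNMT3A": (0.08, 0.12), "TET2": (0.10, 0.12), "JAK2": (1.09, 0.60),
    "PPM1D": (0.15, 0.15), "ASXL1": (0.05, 0.20), "SF3B1": (0.12, 0.15),
    "SRSF2": (0.12, 0.15), "TP53": (0.10, 0.15), "GNAS": (0.08, 0.12),
    "KRAS": (0.10, 0.15), "IDH2": (0.10, 0.15),
}

FALLBACK_GENE_GROWTH = (0.10, 0.15)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic two-timepoint cohort.

    Defaults mirror the cohort the pipeline is built for: ~1725x mean
    depth, first-draw age 65 +/- 15, one-to-12.5-year sampling gaps,
    mutation counts 66/26/8% for 1/2/3+, and clone VAFs at first draw
    log-uniform on [2%, 30%].  ``architecture_prob`` is the chance a
    two-mutation individual is nested sub-clonal rather than carrying
    distinct clones.  ``covariate_effects`` injects additive effects of
    centred numeric covariates on the growth rate (zero by default, the
    no-association null).
    """

    n_individuals: int = 101
    seed: int = 0
    gene_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQUENCIES))
    gene_growth: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_GROWTH))
    mutation_count_probs: tuple[float, float, float] = (0.66, 0.26, 0.08)
    age_mean: float = 65.0
    age_sd: float = 15.0
    dt_range: tuple[float, float] = (1.0, 12.5)
    depth_mean: float = 1725.0
    vaf1_bounds: tuple[float, float] = (0.02, 0.30)
    architecture_prob: float = 0.54
    subclone_cf_sd: float = 0.05
    subclone_frac_range: tuple[float, float] = (0.2, 0.95)
    blood_cancer_prob: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, probs in (("mutation_count_probs", self.mutation_count_probs),
                            ("gene_frequencies", tuple(self.gene_frequencies.values()))):
            if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0 < self.dt_range[0] <= self.dt_range[1]:
            raise ValueError("dt_range must be positive and ordered")


@dataclass
class SimClone:
    """One simulated driver mutation with truth and observed reads."""

    individual_id: str
    gene: str
    contig: str
    pos: int
    ref: str
    alt: str
    protein_change: str | None
    true_frac1: float  # mutant cell fraction at draw 1
    true_frac2: float
    dt_years: float
    role: str  # single | distinct | parent | child
    depth1: int = 0
    alt1: int = 0
    depth2: int = 0
    alt2: int = 0

    @property
    def true_vaf1(self) -> float:
        return self.true_frac1 / 2

    @property
    def true_vaf2(self) -> float:
        return self.true_frac2 / 2

    @property
    def true_cf(self) -> float:
        """Realized annual growth rate implied by the true VAFs."""
        return float(np.expm1(np.log(self.true_vaf2 / self.true_vaf1) / self.dt_years))


@dataclass
class SimIndividual:
    individual_id: str
    age1: float
    date1: date
    date2: date
    dt_years: float
    sex: str
    race: str
    ethnicity: str
    bmi: float
    height: float
    blood_cancer_flag: bool
    architecture: str | None  # sub-clone | distinct | None (not two clones)
    clones: list[SimClone]


@dataclass
class SimCohort:
    """A simulated cohort: configuration, truth, and observed reads."""

    config: SimConfig
    individuals: list[SimIndividual]
    panel: PanelDefinition

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            for c in ind.clones:
                rows.append({
                    "individual_id": c.individual_id, "gene": c.gene,
                    "contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                    "true_vaf1": c.true_vaf1, "true_vaf2": c.true_vaf2,
                    "dt_years": c.dt_years, "true_cf": c.true_cf,
                    "role": c.role, "architecture": ind.architecture,
                    "n_mutations": len(ind.clones),
                    "depth1": c.depth1, "alt1": c.alt1,
                    "depth2": c.depth2, "alt2": c.alt2,
                })
        return pd.DataFrame(rows)

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            for tp, (d, age) in enumerate(
                ((ind.date1, ind.age1), (ind.date2, ind.age1 + ind.dt_years)),
                start=1,
            ):
                rows.append({
                    "individual_id": ind.individual_id,
                    "sample_id": f"{ind.individual_id}_T{tp}",
                    "timepoint": tp,
                    "draw_date": d.isoformat(),
                    "age": round(age, 2),
                    "sex": ind.sex, "race": ind.race, "ethnicity": ind.ethnicity,
                    "bmi": round(ind.bmi, 2), "height": round(ind.height, 1),
                    "blood_cancer_flag": int(ind.blood_cancer_flag),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequencing noise
# ---------------------------------------------------------------------------

def sample_reads(
    true_vaf: float,
    depth_mean: float,
    rng: np.random.Generator,
    fixed_depth: bool = False,
) -> tuple[int, int]:
    """Draw (depth, alt_reads) for one site: Poisson depth, binomial alts.

    With ``fixed_depth`` the depth is exactly ``depth_mean`` (the
    textbook binomial model used for analytic cross-checks).
    """
    if not 0 <= true_vaf <= 1:
        raise ValueError("true_vaf must be in [0, 1]")
    depth = int(depth_mean) if fixed_depth else int(rng.poisson(depth_mean))
    alt = int(rng.binomial(depth, true_vaf)) if depth > 0 else 0
    return depth, alt


def detection_probability(
    true_vaf: float,
    depth: float,
    min_alt_reads: int = 3,
    poisson_depth: bool = False,
) -> float:
    """Analytic P(alt_reads >= min_alt_reads) at a given depth and VAF.

    Fixed depth: binomial upper tail.  Poisson depth: the alt count is
    Poisson-thinned, alt ~ Poisson(depth * vaf), so the tail is Poisson.
    """
    if poisson_depth:
        return float(stats.poisson.sf(min_alt_reads - 1, depth * true_vaf))
    return float(stats.binom.sf(min_alt_reads - 1, int(depth), true_vaf))


def simulate_dilution_series(
    het_vaf: float = 0.5,
    ratios: Sequence[float] = (1.0, 0.5, 0.1, 0.05, 0.02, 0.01, 0.006, 0.002),
    depth_mean: float = 2000.0,
    n_replicates: int = 10_000,
    min_alt_reads: int = 3,
    seed: int = 0,
    fixed_depth: bool = False,
) -> pd.DataFrame:
    """In-silico limiting-dilution series: detection rate vs expected VAF.

    A heterozygous variant (VAF ``het_vaf``) is mixed into a wild-type
    background at each ratio, so the expected VAF is het_vaf * ratio.
    Per ratio the observed VAF and the detection rate (alt reads >=
    ``min_alt_reads``) are estimated over replicates, with the analytic
    tail probability alongside.  This probes the depth-driven limit of
    detection: at ~2000x a 1% VAF is detected essentially always, while
    detection degrades toward ~0.3%.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        if not 0 < ratio <= 1:
            raise ValueError("ratios must be in (0, 1]")
        expected_vaf = het_vaf * ratio
        if fixed_depth:
            depths = np.full(n_replicates, int(depth_mean))
        else:
            depths = rng.poisson(depth_mean, size=n_replicates)
        alts = rng.binomial(depths, expected_vaf)
        detected = alts >= min_alt_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            obs_vaf = np.where(depths > 0, alts / np.maximum(depths, 1), np.nan)
        rows.append({
            "ratio": ratio,
            "expected_vaf": expected_vaf,
            "mean_observed_vaf": float(np.nanmean(obs_vaf)),
            "detection_rate": float(detected.mean()),
            "analytic_detection_prob": detection_probability(
                expected_vaf, depth_mean, min_alt_reads,
                poisson_depth=not fixed_depth),
            "mean_relative_vaf_error": float(
                np.nanmean(np.abs(obs_vaf - expected_vaf)) / expected_vaf),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

class _PositionAllocator:
    """Deterministic unique genomic positions within panel intervals."""

    def __init__(self, panel: PanelDefinition) -> None:
        self._slots: dict[str, list[tuple[str, int]]] = {}
        for gene in panel.genes:
            slots = []
            for contig, start, end in gene.intervals:
                slots.extend((contig, p + 1) for p in range(start, end))  # 1-based
            self._slots[gene.symbol] = slots
        self._counters: dict[str, int] = {g: 0 for g in self._slots}
        self._alts = ("A", "G", "T")

    def allocate(self, gene: str) -> tuple[str, int, str, str]:
        slots = self._slots[gene]
        k = self._counters[gene]
        self._counters[gene] = k + 1
        contig, pos = slots[k % len(slots)]
        return contig, pos, "C", self._alts[(k // len(slots)) % len(self._alts)]


_HOTSPOTS = {"JAK2": ("V617F",), "DNMT3A": ("R882H", "R882C")}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = -0.999) -> float:
    """Normal draw truncated below (growth rate cannot reach -100%)."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > lower:
            return float(x)
    return lower


def simulate_cohort(config: SimConfig, panel: PanelDefinition | None = None) -> SimCohort:
    """Draw a full synthetic cohort with ground truth and observed reads.

    Deterministic given ``config`` (including its seed).  Clone cell
    fractions are kept feasible: distinct clones of one individual are
    scaled so their total fraction stays below 1 at both draws, and a
    nested child's fraction is capped at its parent's.  The realized
    growth rate (``SimClone.true_cf``) reflects these caps and is the
    recovery target for the estimation pipeline.
    """
    panel = panel or load_panel()
    rng = np.random.default_rng(config.seed)
    alloc = _PositionAllocator(panel)
    genes = sorted(config.gene_frequencies)
    gene_probs = np.array([config.gene_frequencies[g] for g in genes])
    base_date = date(2005, 1, 1)
    width = len(str(max(config.n_individuals, 1)))

    individuals: list[SimIndividual] = []
    for i in range(config.n_individuals):
        iid = f"IND{i + 1:0{width}d}"
        age1 = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 95))
        dt_days = int(rng.integers(round(config.dt_range[0] * 365.25),
                                   round(config.dt_range[1] * 365.25) + 1))
        dt_years = dt_days / 365.25
        date1 = base_date + timedelta(days=int(rng.integers(0, 3651)))
        sex = "F" if rng.random() < 0.60 else "M"
        race = "White" if rng.random() < 0.81 else ("Black" if rng.random() < 0.7 else "Asian")
        ethnicity = "Not Hispanic" if rng.random() < 0.95 else "Hispanic"
        bmi = float(np.clip(rng.normal(29, 6), 15, 60))
        height = float(np.clip(rng.normal(170, 10), 140, 210))
        blood_cancer = bool(rng.random() < config.blood_cancer_prob)

        n_mut = 1 + int(rng.choice(3, p=np.asarray(config.mutation_count_probs)))
        cov_shift = 0.0
        values = {"bmi": bmi, "height": height, "age": age1}
        centres = {"bmi": 29.0, "height": 170.0, "age": config.age_mean}
        for cov, beta in config.covariate_effects.items():
            if cov in values:
                cov_shift += beta * (values[cov] - centres[cov])

        def draw_clone(role: str) -> SimClone:
            gene = genes[int(rng.choice(len(genes), p=gene_probs))]
            mean, sd = config.gene_growth.get(gene, FALLBACK_GENE_GROWTH)
            cf = _truncated_normal(rng, mean + cov_shift, sd)
            lo, hi = np.log(config.vaf1_bounds)
            vaf1 = float(np.exp(rng.uniform(lo, hi)))
            frac1 = 2 * vaf1
            frac2 = min(frac1 * (1 + cf) ** dt_years, 1.0)
            contig, pos, ref, alt = alloc.allocate(gene)
            hotspots = _HOTSPOTS.get(gene)
            protein = None
            if hotspots and rng.random() < 0.5:
                protein = hotspots[int(rng.integers(len(hotspots)))]
            return SimClone(
                individual_id=iid, gene=gene, contig=contig, pos=pos,
                ref=ref, alt=alt, protein_change=protein,
                true_frac1=frac1, true_frac2=frac2, dt_years=dt_years, role=role,
            )

        architecture: str | None = None
        if n_mut == 1:
            clones = [draw_clone("single")]
        elif n_mut == 2 and rng.random() < config.architecture_prob:
            architecture = "sub-clone"
            parent = draw_clone("parent")
            child = draw_clone("child")
            u = rng.uniform(*config.subclone_frac_range)
            child.true_frac1 = parent.true_frac1 * u
            parent_cf = parent.true_cf
            child_cf = parent_cf + rng.normal(0, config.subclone_cf_sd)
            child.true_frac2 = min(
                child.true_frac1 * (1 + max(child_cf, -0.999)) ** dt_years,
                parent.true_frac2,
            )
            clones = [parent, child]
        else:
            if n_mut == 2:
                architecture = "distinct"
            clones = [draw_clone("distinct") for _ in range(n_mut)]
            for tp in ("true_frac1", "true_frac2"):
                total = sum(getattr(c, tp) for c in clones)
                if total > 0.96:
                    for c in clones:
                        setattr(c, tp, getattr(c, tp) * 0.96 / total)

        for c in clones:
            c.depth1, c.alt1 = sample_reads(c.true_vaf1, config.depth_mean, rng)
            c.depth2, c.alt2 = sample_reads(c.true_vaf2, config.depth_mean, rng)

        individuals.append(SimIndividual(
            individual_id=iid, age1=age1, date1=date1,
            date2=date1 + timedelta(days=dt_days), dt_years=dt_years,
            sex=sex, race=race, ethnicity=ethnicity, bmi=bmi, height=height,
            blood_cancer_flag=blood_cancer, architecture=architecture,
            clones=clones,
        ))
    logger.info("simulated cohort: %d individuals, %d clones",
                len(individuals), sum(len(i.clones) for i in individuals))
    return SimCohort(config=config, individuals=individuals, panel=panel)


def cohort_to_calls(cohort: SimCohort):
    """Observed reads as in-memory VariantCall records (both timepoints).

    Equivalent to writing fixtures and re-reading the VCF, minus the
    serialization: handy for repeated-simulation studies.  Zero-alt
    observations are omitted, as a caller would.
    """
    from .panel_and_variants import VariantCall

    calls = []
    for ind in cohort.individuals:
        for c in ind.clones:
            for tp, depth, alt in ((1, c.depth1, c.alt1), (2, c.depth2, c.alt2)):
                if depth <= 0 or alt <= 0:
                    continue
                calls.append(VariantCall(
                    individual_id=ind.individual_id, timepoint=tp,
                    contig=c.contig, pos=c.pos, ref=c.ref, alt=c.alt,
                    depth=depth, alt_reads=alt, vaf=alt / depth,
                    gene=c.gene, protein_change=c.protein_change,
                    consequence="missense",
                ))
    return calls


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=chipdyn-synthetic
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change (HGVS-p short)">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_fixtures(cohort: SimCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the observed VCF plus metadata and ground-truth TSVs.

    The VCF is a single multi-sample file (two samples per individual,
    ``<IND>_T1``/``<IND>_T2``), one record per simulated mutation with
    GT:DP:AD populated for the carrier's samples and missing for all
    others.  Files round-trip losslessly through the ingestion module.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples: list[str] = []
    for ind in cohort.individuals:
        samples.extend((f"{ind.individual_id}_T1", f"{ind.individual_id}_T2"))
    sample_index = {s: i for i, s in enumerate(samples)}

    records = []
    for ind in cohort.individuals:
        for c in ind.clones:
            records.append((c.contig, c.pos, ind.individual_id, c))
    records.sort(key=lambda r: (r[0], r[1], r[2], r[3].alt))

    vcf_path = out_dir / "cohort.vcf"
    missing = "./.:.:.,."
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = sorted({r[0] for r in records})
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, pos, iid, c in records:
            cells = [missing] * len(samples)
            for tp, depth, alt in ((1, c.depth1, c.alt1), (2, c.depth2, c.alt2)):
                si = sample_index[f"{iid}_T{tp}"]
                cells[si] = f"0/1:{depth}:{depth - alt},{alt}"
            info = f"GENE={c.gene};CSQ_CLASS=missense"
            if c.protein_change:
                info += f";PCHANGE={c.protein_change}"
            fh.write(
                f"{contig}\t{pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\t"
                f"GT:DP:AD\t" + "\t".join(cells) + "\n"
            )

    meta_path = out_dir / "metadata.tsv"
    cohort.metadata_frame().to_csv(meta_path, sep="\t", index=False)
    truth_path = out_dir / "truth.tsv"
    cohort.truth_frame().to_csv(truth_path, sep="\t", index=False)
    logger.info("fixtures written to %s (%d records, %d samples)",
                out_dir, len(records), len(samples))
    return {"vcf": vcf_path, "metadata": meta_path, "truth": truth_path}
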