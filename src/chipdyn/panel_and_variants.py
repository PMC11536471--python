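"""Panel definition, variant-call ingestion, and CHIP filtering.

This module turns raw somatic variant calls (Mutect2-style VCF with
per-sample ``DP``/``AD``) into the unit of longitudinal analysis: a
:class:`ClonePair`, one driver mutation observed (or imputed) at two
blood draws from the same individual.

The CHIP call set is defined by three per-call filters — total read
depth >= 100, alt-supporting reads >= 3, and VAF >= 2% — applied over a
fixed driver-gene panel.  A mutation that passes the filters at only
one timepoint is still paired: the other timepoint's VAF is rescued
from any sub-threshold raw call with enough alt reads, and otherwise
imputed at the assay's lower detection limit (0.001).

Coordinates: panel intervals are BED (0-based, half-open); VCF
positions are 1-based.  The conversion lives in :func:`vcf_pos_to_bed`
and nowhere else.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("chipdyn")

#: Driver genes targeted by the default CHIP panel.
DEFAULT_PANEL_GENES = (
    "ASXL1", "ASXL2", "BRCC3", "CBL", "DNMT3A", "ETNK1", "GNAS", "GNB1",
    "IDH1", "IDH2", "JAK2", "KIT", "KRAS", "MPL", "NRAS", "PPM1D",
    "SETBP1", "SF3B1", "SRSF2", "TET2", "TP53", "U2AF1",
)


def vcf_pos_to_bed(pos: int) -> int:
    """Convert a 1-based VCF position to a 0-based BED coordinate."""
    return pos - 1


# ---------------------------------------------------------------------------
# Panel definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGene:
    """One targeted driver gene: a symbol plus its captured intervals.

    Intervals are 0-based half-open ``(contig, start, end)`` tuples,
    normalized (sorted, merged) at load time.
    """

    symbol: str
    intervals: tuple[tuple[str, int, int], ...]
    capture_mode: str = "full-gene"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"gene {self.symbol}: no intervals")
        if self.capture_mode not in ("full-gene", "hotspot-region"):
            raise ValueError(
                f"gene {self.symbol}: unknown capture_mode {self.capture_mode!r}"
            )

    @property
    def span_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, contig: str, bed_pos: int) -> bool:
        return any(
            c == contig and start <= bed_pos < end
            for c, start, end in self.intervals
        )


@dataclass(frozen=True)
class PanelDefinition:
    """The gene whitelist plus targeted territory for a CHIP assay."""

    genes: tuple[PanelGene, ...]
    version: str = "default"

    @property
    def target_bp(self) -> int:
        return sum(g.span_bp for g in self.genes)

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes)

    def gene_at(self, contig: str, vcf_pos: int) -> str | None:
        """Panel gene covering a 1-based VCF position, or None."""
        bed_pos = vcf_pos_to_bed(vcf_pos)
        for gene in self.genes:
            if gene.contains(contig, bed_pos):
                return gene.symbol
        return None


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> tuple[tuple[str, int, int], ...]:
    """Sort and merge overlapping/adjacent intervals per contig."""
    merged: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(intervals):
        if merged and merged[-1][0] == contig and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (contig, prev[1], max(prev[2], end))
        else:
            merged.append((contig, start, end))
    return tuple(merged)


def load_panel(path: str | Path | None = None, version: str | None = None) -> PanelDefinition:
    """Load a panel from a BED file (contig, start, end, gene[, capture_mode]).

    With ``path=None`` the shipped default 22-gene CHIP panel is loaded.
    Intervals are merged per gene; a gene appearing with two different
    capture modes is rejected.
    """
    if path is None:
        ref = resources.files("chipdyn") / "data" / "default_panel.bed"
        with resources.as_file(ref) as p:
            return load_panel(p, version=version or "chipdyn-default-22gene")

    path = Path(path)
    by_gene: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    modes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-separated fields "
                    f"(contig, start, end, gene), got {len(fields)}"
                )
            contig, start_s, end_s, symbol = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not symbol or end <= start:
                raise ValueError(f"{path}:{lineno}: empty gene or end <= start")
            mode = fields[4] if len(fields) > 4 and fields[4] else "full-gene"
            if symbol in modes and modes[symbol] != mode:
                raise ValueError(
                    f"{path}:{lineno}: gene {symbol} listed with conflicting "
                    f"capture modes ({modes[symbol]!r} vs {mode!r})"
                )
            modes[symbol] = mode
            by_gene[symbol].append((contig, start, end))

    genes = tuple(
        PanelGene(symbol=sym, intervals=_merge_intervals(ivals), capture_mode=modes[sym])
        for sym, ivals in sorted(by_gene.items())
    )
    panel = PanelDefinition(genes=genes, version=version or str(path))
    logger.info(
        "loaded panel %s: %d genes, %d bp targeted",
        panel.version, len(panel.genes), panel.target_bp,
    )
    return panel


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> None:
    """Serialize a panel back to 5-column BED (round-trips through load_panel)."""
    with open(path, "w") as fh:
        for gene in panel.genes:
            for contig, start, end in gene.intervals:
                fh.write(f"{contig}\t{start}\t{end}\t{gene.symbol}\t{gene.capture_mode}\n")


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """One somatic call in one sample (one alt allele of one VCF record)."""

    individual_id: str
    timepoint: int
    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float
    gene: str | None = None
    protein_change: str | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"{self.individual_id} {self.contig}:{self.pos}: "
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
            )

    @property
    def mutation_key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterPolicy:
    """CHIP variant filters: depth, alt-read support, and VAF thresholds.

    Calls are retained when depth >= ``min_depth``, alt reads >=
    ``min_alt_reads`` and VAF >= ``min_vaf`` (boundary values pass).
    ``floor_vaf`` is the imputation value for a timepoint with no usable
    signal, reflecting the assay's lower detection limit.
    """

    min_depth: int = 100
    min_alt_reads: int = 3
    min_vaf: float = 0.02
    rescue_cross_timepoint: bool = True
    floor_vaf: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.floor_vaf < self.min_vaf <= 1:
            raise ValueError("require 0 < floor_vaf < min_vaf <= 1")
        if self.min_alt_reads < 1 or self.min_depth < 1:
            raise ValueError("min_alt_reads and min_depth must be >= 1")


def _resolve_sample_map(sample_map) -> dict[str, tuple[str, int]]:
    """Normalize sample metadata to {sample_id: (individual_id, timepoint)}."""
    if isinstance(sample_map, pd.DataFrame):
        required = {"sample_id", "individual_id", "timepoint"}
        missing = required - set(sample_map.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        return {
            str(row.sample_id): (str(row.individual_id), int(row.timepoint))
            for row in sample_map.itertuples()
        }
    return {k: (str(v[0]), int(v[1])) for k, v in dict(sample_map).items()}


def read_variants(
    vcf_path: str | Path,
    panel: PanelDefinition,
    sample_map,
) -> list[VariantCall]:
    """Read per-sample somatic calls from a VCF into VariantCall records.

    One record is emitted per alt allele per sample carrying at least one
    alt-supporting read.  VAF is recomputed as AD/DP rather than taken
    from caller AF tags so that calls from different callers are
    comparable.  Calls outside every panel interval get ``gene=None``.

    Raises if a sample name cannot be mapped to (individual, timepoint)
    or if a record lacks per-sample DP/AD.
    """
    from cyvcf2 import VCF

    mapping = _resolve_sample_map(sample_map)
    vcf = VCF(str(vcf_path))
    unmappable = [s for s in vcf.samples if s not in mapping]
    if unmappable:
        raise ValueError(
            f"{vcf_path}: sample names not in metadata: {unmappable[:5]}"
        )
    samples = list(vcf.samples)
    gene_info_tags = ("GENE",)

    calls: list[VariantCall] = []
    for record in vcf:
        try:
            dp = record.format("DP")
            ad = record.format("AD")
        except KeyError:
            dp = ad = None
        if dp is None or ad is None:
            raise ValueError(
                f"{vcf_path}: {record.CHROM}:{record.POS} lacks per-sample DP/AD"
            )
        gene = panel.gene_at(record.CHROM, record.POS)
        annotated_gene = None
        for tag in gene_info_tags:
            annotated_gene = record.INFO.get(tag)
            if annotated_gene:
                break
        if annotated_gene and gene and annotated_gene != gene:
            logger.warning(
                "%s:%d annotated gene %s disagrees with panel gene %s; using panel",
                record.CHROM, record.POS, annotated_gene, gene,
            )
        protein_change = record.INFO.get("PCHANGE") or None
        consequence = record.INFO.get("CSQ_CLASS") or None
        for si, sample in enumerate(samples):
            depth = int(dp[si][0] if dp.ndim > 1 else dp[si])
            if depth <= 0:
                continue
            for ai, alt in enumerate(record.ALT):
                alt_reads = int(ad[si][ai + 1])
                if alt_reads <= 0:
                    continue
                individual_id, timepoint = mapping[sample]
                calls.append(
                    VariantCall(
                        individual_id=individual_id,
                        timepoint=timepoint,
                        contig=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        depth=depth,
                        alt_reads=min(alt_reads, depth),
                        vaf=min(alt_reads, depth) / depth,
                        gene=gene,
                        protein_change=protein_change,
                        consequence=consequence,
                    )
                )
    logger.info("read %d calls from %s", len(calls), vcf_path)
    return calls


def filter_chip(calls: Sequence[VariantCall], policy: FilterPolicy | None = None) -> list[VariantCall]:
    """Apply the CHIP filters; return the retained calls.

    A call is retained iff depth >= min_depth AND alt_reads >=
    min_alt_reads AND vaf >= min_vaf AND it falls in a panel gene.
    Removal counts are logged with per-rule attribution (a call can fail
    several rules at once).
    """
    policy = policy or FilterPolicy()
    retained: list[VariantCall] = []
    failures: Counter[str] = Counter()
    for call in calls:
        ok = True
        if call.depth < policy.min_depth:
            failures["low_depth"] += 1
            ok = False
        if call.alt_reads < policy.min_alt_reads:
            failures["low_alt_reads"] += 1
            ok = False
        if call.vaf < policy.min_vaf:
            failures["low_vaf"] += 1
            ok = False
        if call.gene is None:
            failures["off_panel"] += 1
            ok = False
        if ok:
            retained.append(call)
    logger.info(
        "filter_chip: %d/%d retained (failures by rule: %s)",
        len(retained), len(calls), dict(failures),
    )
    return retained


# ---------------------------------------------------------------------------
# Metadata and timepoint pairing
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "individual_id", "sample_id", "timepoint", "draw_date", "age", "sex",
    "race", "ethnicity", "bmi", "height", "blood_cancer_flag",
)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Load the sample-metadata TSV (one row per sample)."""
    meta = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "sample_id": str})
    required = {"individual_id", "sample_id", "timepoint"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return meta


def dt_years_by_individual(meta: pd.DataFrame) -> dict[str, float]:
    """Elapsed years between the two draws of each individual.

    Draw dates take precedence (difference in days / 365.25); the age
    difference is the fallback.  Individuals without two timepoints are
    omitted; a non-positive elapsed time raises.
    """
    dt: dict[str, float] = {}
    has_dates = "draw_date" in meta.columns and meta["draw_date"].notna().any()
    for individual, grp in meta.groupby("individual_id"):
        grp = grp.sort_values("timepoint")
        if grp["timepoint"].nunique() < 2:
            logger.warning("individual %s has <2 timepoints; skipped", individual)
            continue
        t1 = grp[grp.timepoint == 1].iloc[0]
        t2 = grp[grp.timepoint == 2].iloc[0]
        if has_dates and pd.notna(t1.get("draw_date")) and pd.notna(t2.get("draw_date")):
            days = (pd.Timestamp(t2.draw_date) - pd.Timestamp(t1.draw_date)).days
            years = days / 365.25
        elif "age" in meta.columns and pd.notna(t1.get("age")) and pd.notna(t2.get("age")):
            years = float(t2.age) - float(t1.age)
        else:
            logger.warning("individual %s lacks dates and ages; skipped", individual)
            continue
        if years <= 0:
            raise ValueError(f"individual {individual}: elapsed time {years} <= 0")
        dt[str(individual)] = years
    return dt


def excluded_individuals(meta: pd.DataFrame) -> set[str]:
    """Individuals flagged with a disqualifying blood-cancer diagnosis."""
    if "blood_cancer_flag" not in meta.columns:
        return set()
    flagged = meta.loc[
        meta["blood_cancer_flag"].astype(str).str.lower().isin(("1", "true", "yes")),
        "individual_id",
    ]
    return set(flagged.astype(str))


@dataclass(frozen=True)
class ClonePair:
    """One driver mutation tracked across two timepoints of one individual."""

    individual_id: str
    gene: str
    mutation_key: tuple[str, int, str, str]
    vaf1: float
    vaf2: float
    dt_years: float
    pass_t1: bool
    pass_t2: bool
    imputed_t1: bool = False
    imputed_t2: bool = False
    protein_change: str | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.dt_years <= 0:
            raise ValueError(f"{self.individual_id}: dt_years must be > 0")
        if not (0 < self.vaf1 <= 1 and 0 < self.vaf2 <= 1):
            raise ValueError(f"{self.individual_id}: VAFs must be in (0, 1]")
        if not (self.pass_t1 or self.pass_t2):
            raise ValueError("a ClonePair must pass filters at >=1 timepoint")


def pair_timepoints(
    retained: Sequence[VariantCall],
    all_calls: Sequence[VariantCall],
    policy: FilterPolicy,
    metadata: pd.DataFrame,
) -> list[ClonePair]:
    """Pair each filter-passing mutation across the two timepoints.

    For every mutation passing the CHIP filters at >=1 timepoint, the
    other timepoint's VAF comes from (in order): its own passing call; a
    sub-threshold raw call with alt_reads >= min_alt_reads (rescue,
    usable evidence below the 2% CHIP threshold); the ``floor_vaf``
    imputation, standing in for a clone below the detection limit.

    Individuals flagged for blood cancer, and mutation identity, are
    taken as given: identity is an exact (contig, pos, ref, alt) match.
    """
    dt_map = dt_years_by_individual(metadata)
    dropped = excluded_individuals(metadata)

    def key(call: VariantCall) -> tuple:
        return (call.individual_id, *call.mutation_key)

    retained_keys: dict[tuple, dict[int, VariantCall]] = defaultdict(dict)
    for call in retained:
        retained_keys[key(call)][call.timepoint] = call
    raw_lookup: dict[tuple, dict[int, VariantCall]] = defaultdict(dict)
    for call in all_calls:
        prev = raw_lookup[key(call)].get(call.timepoint)
        if prev is None or call.alt_reads > prev.alt_reads:
            raw_lookup[key(call)][call.timepoint] = call

    pairs: list[ClonePair] = []
    for k in sorted(retained_keys):
        individual_id = k[0]
        if individual_id in dropped:
            continue
        if individual_id not in dt_map:
            logger.warning(
                "individual %s: no usable two-timepoint metadata; mutation %s skipped",
                individual_id, k[1:],
            )
            continue
        per_tp = retained_keys[k]
        vafs: dict[int, float] = {}
        imputed: dict[int, bool] = {}
        anchor = next(iter(per_tp.values()))
        for tp in (1, 2):
            if tp in per_tp:
                vafs[tp] = per_tp[tp].vaf
                imputed[tp] = False
                continue
            rescue = raw_lookup.get(k, {}).get(tp)
            if (
                policy.rescue_cross_timepoint
                and rescue is not None
                and rescue.alt_reads >= policy.min_alt_reads
            ):
                vafs[tp] = rescue.vaf
                imputed[tp] = False
            else:
                vafs[tp] = policy.floor_vaf
                imputed[tp] = True
        pairs.append(
            ClonePair(
                individual_id=individual_id,
                gene=anchor.gene,
                mutation_key=anchor.mutation_key,
                vaf1=vafs[1],
                vaf2=vafs[2],
                dt_years=dt_map[individual_id],
                pass_t1=1 in per_tp,
                pass_t2=2 in per_tp,
                imputed_t1=imputed[1],
                imputed_t2=imputed[2],
                protein_change=anchor.protein_change,
                consequence=anchor.consequence,
            )
        )
    logger.info("pair_timepoints: %d clone pairs from %d retained keys",
                len(pairs), len(retained_keys))
    return pairs


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    cols = ["individual_id", "timepoint", "contig", "pos", "ref", "alt",
            "depth", "alt_reads", "vaf", "gene", "protein_change", "consequence"]
    return pd.DataFrame([{c: getattr(v, c) for c in cols} for v in calls], columns=cols)


def pairs_to_frame(pairs: Sequence[ClonePair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        contig, pos, ref, alt = p.mutation_key
        rows.append({
            "individual_id": p.individual_id, "gene": p.gene,
            "contig": contig, "pos": pos, "ref": ref, "alt": alt,
            "vaf1": p.vaf1, "vaf2": p.vaf2, "dt_years": p.dt_years,
            "pass_t1": p.pass_t1, "pass_t2": p.pass_t2,
            "imputed_t1": p.imputed_t1, "imputed_t2": p.imputed_t2,
            "protein_change": p.protein_change, "consequence": p.consequence,
        })
    return pd.DataFrame(rows, columns=[
        "individual_id", "gene", "contig", "pos", "ref", "alt", "vaf1", "vaf2",
        "dt_years", "pass_t1", "pass_t2", "imputed_t1", "imputed_t2",
        "protein_change", "consequence",
    ])


def pairs_from_frame(frame: pd.DataFrame) -> list[ClonePair]:
    """Inverse of :func:`pairs_to_frame` (clone-pairs TSV -> objects)."""
    pairs = []
    for row in frame.itertuples():
        pairs.append(ClonePair(
            individual_id=str(row.individual_id), gene=str(row.gene),
            mutation_key=(str(row.contig), int(row.pos), str(row.ref), str(row.alt)),
            vaf1=float(row.vaf1), vaf2=float(row.vaf2), dt_years=float(row.dt_years),
            pass_t1=bool(row.pass_t1), pass_t2=bool(row.pass_t2),
            imputed_t1=bool(row.imputed_t1), imputed_t2=bool(row.imputed_t2),
            protein_change=None if pd.isna(row.protein_change) else str(row.protein_change),
            consequence=None if pd.isna(row.consequence) else str(row.consequence),
        ))
    return pairs
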