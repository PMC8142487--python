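"""Readers and writers for the external tables the pipeline consumes.

Every interval type is stored 0-based half-open internally; variant
positions stay 1-based points (VCF-like convention).  Missing numeric
cells are written as ``.`` and accepted as ``.`` or ``NA`` on read.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PREDICTOR_NAMES",
    "N_PATHWAYS",
    "Consequence",
    "AnnotatedVariant",
    "SCNASegment",
    "GeneInterval",
    "MCRDirection",
    "MCRRegion",
    "PathwayGeneSets",
    "VariantDialect",
    "FormatError",
    "ContractError",
    "read_variant_table",
    "write_variant_table",
    "read_scna_segments",
    "write_scna_segments",
    "read_gene_intervals",
    "read_mcr_regions",
    "read_gene_scores",
    "read_gene_sets",
    "read_gene_list",
    "write_predictions",
]

#: Canonical order of the 12 per-variant impact-predictor scores.  This
#: order is frozen: the metapredictor's feature vector and every variant
#: table follow it.
PREDICTOR_NAMES: tuple[str, ...] = (
    "SIFT",
    "PolyPhen2",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "GERP++",
    "PhyloP",
    "CADD",
    "VEST",
    "SiPhy",
    "DANN",
)

#: Number of cancer-related pathway gene sets (binary membership features).
N_PATHWAYS = 21

MISSING_TOKENS = {".", "NA", ""}
MISSING_WRITE_TOKEN = "."


class FormatError(ValueError):
    """A file violates its format contract (bad column, bad cell, empty)."""


class ContractError(ValueError):
    """An operation precondition is violated by otherwise well-formed input."""


class Consequence(str, enum.Enum):
    """Three-way collapse of annotator consequence categories."""

    CODING_NONSYNONYMOUS = "coding_nonsynonymous"
    CODING_OTHER = "coding_other"
    NONCODING = "noncoding"

    @property
    def is_coding(self) -> bool:
        return self is not Consequence.NONCODING


#: Default mapping from annotator consequence strings (ANNOVAR
#: ExonicFunc-style) onto the three-value enum.  Users with a different
#: annotator vocabulary override it through :class:`VariantDialect`.
DEFAULT_CONSEQUENCE_MAP: dict[str, Consequence] = {
    "nonsynonymous SNV": Consequence.CODING_NONSYNONYMOUS,
    "stopgain": Consequence.CODING_NONSYNONYMOUS,
    "stoploss": Consequence.CODING_NONSYNONYMOUS,
    "frameshift insertion": Consequence.CODING_NONSYNONYMOUS,
    "frameshift deletion": Consequence.CODING_NONSYNONYMOUS,
    "nonframeshift insertion": Consequence.CODING_OTHER,
    "nonframeshift deletion": Consequence.CODING_OTHER,
    "synonymous SNV": Consequence.CODING_OTHER,
    "unknown": Consequence.CODING_OTHER,
    "intronic": Consequence.NONCODING,
    "intergenic": Consequence.NONCODING,
    "UTR3": Consequence.NONCODING,
    "UTR5": Consequence.NONCODING,
    "upstream": Consequence.NONCODING,
    "downstream": Consequence.NONCODING,
    "ncRNA": Consequence.NONCODING,
    "splicing": Consequence.NONCODING,
    ".": Consequence.NONCODING,
}


@dataclass(frozen=True)
class VariantDialect:
    """Column-name map and consequence vocabulary for variant tables.

    Defaults match ANNOVAR-multianno-style headers; both are
    configurable because annotator header sets vary between versions.
    """

    chrom: str = "Chr"
    pos: str = "Start"
    ref: str = "Ref"
    alt: str = "Alt"
    gene: str = "Gene"
    consequence: str = "ExonicFunc"
    predictor_columns: Mapping[str, str] = field(
        default_factory=lambda: {name: name for name in PREDICTOR_NAMES}
    )
    phred_noncoding: str = "CADD_phred"
    occurrence: str = "Occurrence"
    patient_id: str = "PatientID"  # optional column
    consequence_map: Mapping[str, Consequence] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MAP)
    )

    def required_columns(self) -> list[str]:
        cols = [self.chrom, self.pos, self.ref, self.alt, self.gene, self.consequence]
        cols.extend(self.predictor_columns[name] for name in PREDICTOR_NAMES)
        cols.extend([self.phred_noncoding, self.occurrence])
        return cols


@dataclass
class AnnotatedVariant:
    """One somatic variant with its consequence class and impact scores.

    ``pos`` is a 1-based point.  ``predictor_scores`` holds the 12 scores
    in :data:`PREDICTOR_NAMES` order with ``None`` marking a missing
    score; ``phred_noncoding`` is the Phred-scaled deleteriousness score
    used for non-coding variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    predictor_scores: dict[str, float | None]
    phred_noncoding: float | None = None
    occurrence: int | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ContractError(f"variant position must be >= 1, got {self.pos}")
        if self.occurrence is not None and self.occurrence < 0:
            raise ContractError(f"occurrence must be >= 0, got {self.occurrence}")
        missing = [n for n in PREDICTOR_NAMES if n not in self.predictor_scores]
        if missing:
            raise ContractError(f"predictor_scores lacks entries for {missing}")

    @property
    def has_complete_scores(self) -> bool:
        return all(self.predictor_scores[n] is not None for n in PREDICTOR_NAMES)

    def score_vector(self) -> list[float | None]:
        return [self.predictor_scores[n] for n in PREDICTOR_NAMES]


@dataclass(frozen=True)
class SCNASegment:
    """A copy-number segment with log2 copy-ratio, 0-based half-open."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ContractError(
                f"segment start must be < end, got [{self.start}, {self.end})"
            )
        if not math.isfinite(self.log2_ratio):
            raise ContractError("log2_ratio must be finite")


@dataclass(frozen=True)
class GeneInterval:
    """Genomic extent of one gene, 0-based half-open."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ContractError(
                f"gene interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class MCRDirection(str, enum.Enum):
    AMPLIFICATION = "amplification"
    DELETION = "deletion"


@dataclass(frozen=True)
class MCRRegion:
    """Minimal common region of recurrent amplification or deletion.

    ``density`` is the region's SCNA event density in events per
    megabase; it becomes the gene's copy-number proxy score when a
    gene-level event of matching direction overlaps the region.
    """

    chrom: str
    start: int
    end: int
    direction: MCRDirection
    density: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ContractError(
                f"MCR start must be < end, got [{self.start}, {self.end})"
            )
        if self.density < 0:
            raise ContractError(f"MCR density must be >= 0, got {self.density}")


@dataclass(frozen=True)
class PathwayGeneSets:
    """Ordered collection of exactly 21 named cancer-related pathways."""

    names: tuple[str, ...]
    sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.names) != N_PATHWAYS or len(self.sets) != N_PATHWAYS:
            raise ContractError(
                f"expected {N_PATHWAYS} pathway sets, got {len(self.sets)}"
            )
        if len(set(self.names)) != len(self.names):
            raise ContractError("pathway names must be unique")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_float(cell: object) -> float | None:
    text = str(cell).strip()
    if text in MISSING_TOKENS or (isinstance(cell, float) and pd.isna(cell)):
        return None
    try:
        return float(text)
    except ValueError:
        return None  # unparseable numeric cells become missing


def _parse_int(cell: object) -> int | None:
    value = _parse_float(cell)
    if value is None:
        return None
    return int(value)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    return frame


# ---------------------------------------------------------------------------
# readers

def read_variant_table(
    path: str | Path, dialect: VariantDialect | None = None
) -> list[AnnotatedVariant]:
    """Read a tab-delimited annotated variant table.

    The header must name every required column of the dialect
    (:meth:`VariantDialect.required_columns`); the patient-id column is
    optional.  Numeric cells that fail to parse are treated as missing.
    Consequence strings outside the dialect's map fall back to
    ``noncoding``.
    """
    dialect = dialect or VariantDialect()
    frame = _read_tsv(path)
    for col in dialect.required_columns():
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    has_patient = dialect.patient_id in frame.columns

    variants: list[AnnotatedVariant] = []
    for _, row in frame.iterrows():
        raw_consequence = str(row[dialect.consequence]).strip()
        consequence = dialect.consequence_map.get(raw_consequence, Consequence.NONCODING)
        scores = {
            name: _parse_float(row[dialect.predictor_columns[name]])
            for name in PREDICTOR_NAMES
        }
        pos = _parse_int(row[dialect.pos])
        if pos is None:
            raise FormatError(f"{path}: non-numeric position '{row[dialect.pos]}'")
        variants.append(
            AnnotatedVariant(
                chrom=str(row[dialect.chrom]),
                pos=pos,
                ref=str(row[dialect.ref]),
                alt=str(row[dialect.alt]),
                gene=str(row[dialect.gene]),
                consequence=consequence,
                predictor_scores=scores,
                phred_noncoding=_parse_float(row[dialect.phred_noncoding]),
                occurrence=_parse_int(row[dialect.occurrence]),
                patient_id=str(row[dialect.patient_id]) if has_patient else None,
            )
        )
    return variants


def write_variant_table(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    dialect: VariantDialect | None = None,
) -> None:
    """Write variants back in the dialect's tab-delimited layout."""
    dialect = dialect or VariantDialect()
    # invert the consequence map: first annotator string per enum value
    inverse: dict[Consequence, str] = {}
    for raw, cons in dialect.consequence_map.items():
        inverse.setdefault(cons, raw)
    rows = []
    any_patient = any(v.patient_id is not None for v in variants)
    for v in variants:
        row: dict[str, object] = {
            dialect.chrom: v.chrom,
            dialect.pos: v.pos,
            dialect.ref: v.ref,
            dialect.alt: v.alt,
            dialect.gene: v.gene,
            dialect.consequence: inverse.get(v.consequence, v.consequence.value),
        }
        for name in PREDICTOR_NAMES:
            score = v.predictor_scores[name]
            row[dialect.predictor_columns[name]] = (
                MISSING_WRITE_TOKEN if score is None else repr(score)
            )
        row[dialect.phred_noncoding] = (
            MISSING_WRITE_TOKEN if v.phred_noncoding is None else repr(v.phred_noncoding)
        )
        row[dialect.occurrence] = (
            MISSING_WRITE_TOKEN if v.occurrence is None else str(v.occurrence)
        )
        if any_patient:
            row[dialect.patient_id] = v.patient_id or MISSING_WRITE_TOKEN
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scna_segments(path: str | Path) -> list[SCNASegment]:
    """Read a SEG-style table (chrom, start, end, log2 ratio[, patient]).

    Input coordinates are 1-based inclusive; they are converted to
    0-based half-open so that ``end - start`` equals the inclusive
    length.  An empty file yields an empty list.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    frame = _read_tsv(path)
    required = ["chrom", "start", "end", "log2_ratio"]
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    has_patient = "patient_id" in frame.columns

    segments: list[SCNASegment] = []
    for i, row in frame.iterrows():
        try:
            start1 = int(row["start"])
            end1 = int(row["end"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {i + 1}: non-integer coordinates") from exc
        log2 = _parse_float(row["log2_ratio"])
        if log2 is None:
            raise FormatError(f"{path}: row {i + 1}: non-numeric log2 ratio")
        start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if start0 >= end0:
            raise FormatError(f"{path}: row {i + 1}: start > end after conversion")
        segments.append(
            SCNASegment(
                chrom=str(row["chrom"]),
                start=start0,
                end=end0,
                log2_ratio=log2,
                patient_id=str(row["patient_id"]) if has_patient else None,
            )
        )
    return segments


def write_scna_segments(segments: Sequence[SCNASegment], path: str | Path) -> None:
    """Write segments as SEG-style TSV, re-emitting 1-based inclusive coords."""
    rows = []
    any_patient = any(s.patient_id is not None for s in segments)
    for s in segments:
        row: dict[str, object] = {
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "log2_ratio": repr(s.log2_ratio),
        }
        if any_patient:
            row["patient_id"] = s.patient_id or MISSING_WRITE_TOKEN
        rows.append(row)
    cols = ["chrom", "start", "end", "log2_ratio"] + (["patient_id"] if any_patient else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read a BED file of gene intervals (chrom, start, end, gene name).

    BED is already 0-based half-open.  Duplicate (gene, chrom) records
    collapse to the union extent so one record per gene per chromosome
    remains.
    """
    path = Path(path)
    merged: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 BED columns")
            chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            key = (gene, chrom)
            if key in merged:
                merged[key][0] = min(merged[key][0], start)
                merged[key][1] = max(merged[key][1], end)
            else:
                merged[key] = [start, end]
                order.append(key)
    return [
        GeneInterval(gene=gene, chrom=chrom, start=merged[(gene, chrom)][0], end=merged[(gene, chrom)][1])
        for gene, chrom in order
    ]


def read_mcr_regions(path: str | Path) -> list[MCRRegion]:
    """Read the 5-column MCR table (chrom, start, end, direction, density).

    Coordinates are 1-based inclusive on disk, converted to 0-based
    half-open; direction must be ``amplification`` or ``deletion``.
    """
    frame = _read_tsv(path)
    required = ["chrom", "start", "end", "direction", "density"]
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    regions: list[MCRRegion] = []
    for i, row in frame.iterrows():
        try:
            direction = MCRDirection(str(row["direction"]).strip().lower())
        except ValueError as exc:
            raise FormatError(
                f"{path}: row {i + 1}: unknown direction '{row['direction']}'"
            ) from exc
        density = _parse_float(row["density"])
        if density is None:
            raise FormatError(f"{path}: row {i + 1}: non-numeric density")
        regions.append(
            MCRRegion(
                chrom=str(row["chrom"]),
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                direction=direction,
                density=density,
            )
        )
    return regions


def read_gene_scores(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of prior gene scores (gene, score >= 0)."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene, score)")
    gene_col, score_col = frame.columns[:2]
    scores: dict[str, float] = {}
    for i, row in frame.iterrows():
        value = _parse_float(row[score_col])
        if value is None:
            raise FormatError(f"{path}: row {i + 1}: non-numeric score")
        if value < 0:
            raise FormatError(f"{path}: row {i + 1}: negative prior score")
        scores[str(row[gene_col])] = value
    return scores


def read_gene_sets(path: str | Path) -> PathwayGeneSets:
    """Read pathway gene sets in GMT format (name, description, genes...).

    Exactly 21 sets are required, in file order; duplicate genes within
    one set are deduplicated.
    """
    names: list[str] = []
    sets: list[frozenset[str]] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: GMT line needs name, description and >= 1 gene"
                )
            names.append(parts[0])
            sets.append(frozenset(g for g in parts[2:] if g))
    if len(sets) != N_PATHWAYS:
        raise ContractError(
            f"{path}: expected {N_PATHWAYS} pathway sets, got {len(sets)}"
        )
    return PathwayGeneSets(names=tuple(names), sets=tuple(sets))


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one symbol per line)."""
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def write_gene_intervals(genes: Sequence[GeneInterval], path: str | Path) -> None:
    """Write gene intervals as 4-column BED (0-based half-open, as stored)."""
    with open(path, "w") as handle:
        for g in genes:
            handle.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\n")


def write_mcr_regions(regions: Sequence[MCRRegion], path: str | Path) -> None:
    """Write the MCR table, re-emitting 1-based inclusive coordinates."""
    rows = [
        {
            "chrom": m.chrom,
            "start": m.start + 1,
            "end": m.end,
            "direction": m.direction.value,
            "density": repr(m.density),
        }
        for m in regions
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "density"]).to_csv(
        path, sep="\t", index=False
    )


def write_gene_scores(scores: Mapping[str, float], path: str | Path) -> None:
    """Write a two-column prior gene-score TSV."""
    with open(path, "w") as handle:
        handle.write("gene\tscore\n")
        for gene in scores:
            handle.write(f"{gene}\t{scores[gene]!r}\n")


def write_gene_sets(sets: PathwayGeneSets, path: str | Path) -> None:
    """Write pathway gene sets in GMT format."""
    with open(path, "w") as handle:
        for name, genes in zip(sets.names, sets.sets):
            handle.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(set(genes)):
            handle.write(f"{gene}\n")


def write_predictions(
    results: Iterable[Mapping[str, object]],
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write ranked predictions as TSV.

    ``results`` are mappings with keys ``gene``, ``cancer_type``,
    ``probability``, ``predicted_label``, already sorted by probability
    descending.  Probabilities are rendered with fixed decimal precision
    so the byte output is deterministic for fixed input.
    """
    rows = list(results)
    probs = [float(r["probability"]) for r in rows]
    if any(probs[i] < probs[i + 1] for i in range(len(probs) - 1)):
        raise ContractError("results must be sorted by probability descending")
    with open(path, "w") as handle:
        handle.write("gene\tcancer_type\tprobability\tpredicted_label\n")
        for r in rows:
            handle.write(
                f"{r['gene']}\t{r['cancer_type']}\t"
                f"{float(r['probability']):.{precision}f}\t{r['predicted_label']}\n"
            )
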