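"""Domain types and format I/O.

All genomic coordinates are held internally as 0-based half-open intervals;
conversion to and from 1-based closed conventions (GFF3) happens only at the
file boundary. Readers validate invariants eagerly so downstream code can
assume well-formed objects.

Supported formats: GFF3 and BED12 (gene models), BED6 and ENCODE narrowPeak
(ChIP peaks), GMT (gene sets), and TSV for expression tables and genotype
panels. Writers emit a ``#!`` header comment recording the tool version and
the parameters used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, UsageError, ValidationError

__all__ = [
    "GeneModel",
    "Peak",
    "PeakSet",
    "ExpressionRecord",
    "GenotypePanel",
    "read_gene_models",
    "write_gene_models",
    "read_peaks",
    "write_peaks",
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "read_genotype_panels",
    "write_genotype_panels",
]

_VERSION = "0.1.0"


def _header_comment(**params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"#! cotarget version={_VERSION} {kv}".rstrip()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates and identifiers; the anchor for promoter,
    gene-body and 3' windows.

    ``start``/``end`` are 0-based half-open. The transcription start and end
    sites are strand-aware single-base positions: for a ``+`` gene the TSS is
    ``start`` and the TES is ``end - 1``; for a ``-`` gene they swap.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A ChIP binding interval (0-based half-open) with optional summit.

    The *representative point* used throughout the pipeline is the summit if
    present, else the interval midpoint ``floor((start+end)/2)`` — peak
    sources mix ChIP-chip (no summit) and ChIP-seq.
    """

    chrom: str
    start: int
    end: int
    peak_id: str
    summit: int | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"peak {self.peak_id}: require start < end, got [{self.start}, {self.end})"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.peak_id}: summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def point(self) -> int:
        """Representative single-bp position: summit, else midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """An ordered collection of peaks for one factor."""

    factor_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(
                f"peak set {self.factor_label}: duplicate peak_id {dup!r}"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's differential-expression measurement in one experiment."""

    gene_id: str
    log2fc: float
    p_value: float
    experiment_id: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id} ({self.experiment_id}): "
                f"p_value {self.p_value} outside [0, 1]"
            )


@dataclass
class GenotypePanel:
    """WT / single-mutant / single-mutant / double-mutant expression panel
    for one gene: replicate relative-expression values (WT-normalized,
    positive) per genotype label (WT, mutA, mutB, mutAB)."""

    gene_id: str
    measurements: dict[str, list[float]]

    REQUIRED = ("WT", "mutA", "mutB", "mutAB")

    def __post_init__(self):
        for g in self.REQUIRED:
            reps = self.measurements.get(g)
            if reps is None or len(reps) < 2:
                raise ValidationError(
                    f"gene {self.gene_id}: genotype {g!r} needs >= 2 replicates"
                )
        for g, reps in self.measurements.items():
            if any(v <= 0 for v in reps):
                raise ValidationError(
                    f"gene {self.gene_id}: non-positive value in genotype {g!r}"
                )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_GFF3_ATTR_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def _parse_gff3_gene(fieldsv: list[str], path, lineno: int) -> GeneModel:
    chrom, _source, _type, start, end, _score, strand, _phase, attrs = fieldsv
    m = _GFF3_ATTR_ID.search(attrs)
    if not m:
        raise ParseError("no ID= or gene_id= attribute", path, lineno)
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise ParseError(f"non-integer coordinates {start!r}/{end!r}", path, lineno)
    # GFF3 is 1-based closed; internal is 0-based half-open.
    return GeneModel(
        gene_id=m.group(1).strip(),
        chrom=chrom,
        strand=strand,
        start=start_i - 1,
        end=end_i,
    )


def read_gene_models(path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3, BED12 or a plain TSV.

    GFF3 coordinates (1-based closed) and BED coordinates (0-based half-open)
    are both normalized to the internal 0-based half-open convention. The TSV
    dialect has a header ``gene_id chrom strand start end`` with coordinates
    already in the internal convention.

    Raises :class:`ParseError` naming the line on malformed input and
    :class:`ValidationError` on duplicate gene identifiers.
    """
    path = Path(path)
    if format not in ("gff3", "bed12", "tsv"):
        raise UsageError(f"unknown gene-model format {format!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fieldsv = line.split("\t")
            try:
                if format == "gff3":
                    if len(fieldsv) != 9:
                        raise ParseError(
                            f"expected 9 tab-separated fields, got {len(fieldsv)}",
                            path,
                            lineno,
                        )
                    if fieldsv[2] not in ("gene", "mRNA", "transcript"):
                        continue
                    genes.append(_parse_gff3_gene(fieldsv, path, lineno))
                elif format == "bed12":
                    if len(fieldsv) < 6:
                        raise ParseError(
                            f"BED12 needs >= 6 fields, got {len(fieldsv)}", path, lineno
                        )
                    chrom, start, end, name, _score, strand = fieldsv[:6]
                    genes.append(
                        GeneModel(
                            gene_id=name,
                            chrom=chrom,
                            strand=strand,
                            start=int(start),
                            end=int(end),
                        )
                    )
                else:  # tsv
                    if not header_seen:
                        header_seen = True
                        if fieldsv[0] == "gene_id":
                            continue
                    if len(fieldsv) < 5:
                        raise ParseError(
                            f"TSV needs 5 fields, got {len(fieldsv)}", path, lineno
                        )
                    gid, chrom, strand, start, end = fieldsv[:5]
                    genes.append(
                        GeneModel(
                            gene_id=gid,
                            chrom=chrom,
                            strand=strand,
                            start=int(start),
                            end=int(end),
                        )
                    )
            except ParseError:
                raise
            except (ValueError, ValidationError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(str(exc), path, lineno)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path, format: str = "gff3") -> None:
    """Write gene models; GFF3 output converts back to 1-based closed so the
    conversion round-trips bit-exactly."""
    path = Path(path)
    genes = list(genes)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(_header_comment(writer="gene_models", format="gff3") + "\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tcotarget\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        elif format == "tsv":
            fh.write(_header_comment(writer="gene_models", format="tsv") + "\n")
            fh.write("gene_id\tchrom\tstrand\tstart\tend\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")
        else:
            raise UsageError(f"unsupported gene-model output format {format!r}")


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def read_peaks(path, dialect: str = "narrowpeak", factor_label: str | None = None) -> PeakSet:
    """Read a peak set from BED6 or ENCODE narrowPeak.

    narrowPeak column 10 is the summit offset from ``start``; ``-1`` means no
    summit. BED6 peaks carry no summit (the interval midpoint is used as the
    representative point downstream). Peak ids come from the name column when
    present, else are generated as ``<factor>_peak_<i>``.
    """
    path = Path(path)
    if dialect not in ("bed6", "narrowpeak"):
        raise UsageError(f"unknown peak dialect {dialect!r}")
    label = factor_label if factor_label is not None else path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError):
                raise ParseError("malformed BED coordinates", path, lineno)
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"{label}_peak_{len(peaks) + 1}"
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                try:
                    score = float(f[4])
                except ValueError:
                    raise ParseError(f"non-numeric score {f[4]!r}", path, lineno)
            summit = None
            if dialect == "narrowpeak":
                if len(f) < 10:
                    raise ParseError(
                        f"narrowPeak needs 10 fields, got {len(f)}", path, lineno
                    )
                try:
                    offset = int(f[9])
                except ValueError:
                    raise ParseError(f"non-integer summit offset {f[9]!r}", path, lineno)
                if offset >= end - start:
                    raise ValidationError(
                        f"{path}:{lineno}: summit offset {offset} >= peak length {end - start}"
                    )
                if offset >= 0:
                    summit = start + offset
                try:
                    score = float(f[6])  # signalValue as score
                except ValueError:
                    score = score
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, peak_id=name, summit=summit, score=score)
            )
    return PeakSet(factor_label=label, peaks=peaks)


def write_peaks(peakset: PeakSet, path, dialect: str = "narrowpeak") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(writer="peaks", dialect=dialect, factor=peakset.factor_label) + "\n")
        for p in peakset:
            score = p.score if p.score is not None else 0.0
            if dialect == "narrowpeak":
                offset = p.summit - p.start if p.summit is not None else -1
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                    f"{score:g}\t-1\t-1\t{offset}\n"
                )
            elif dialect == "bed6":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score:g}\t.\n")
            else:
                raise UsageError(f"unknown peak dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Expression tables, gene sets, genotype panels
# ---------------------------------------------------------------------------


def read_expression_table(path, experiment_id: str | None = None) -> list[ExpressionRecord]:
    """Read a differential-expression TSV.

    Expected header: ``gene_id  log2fc  p_value`` (one file per experiment;
    the experiment label is then taken from ``experiment_id`` or the file
    stem), or long format with an additional ``experiment_id`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str},
                     float_precision="round_trip")
    required = {"gene_id", "log2fc", "p_value"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"expression table must have columns {sorted(required)}, got {list(df.columns)}",
            path,
        )
    if "experiment_id" not in df.columns:
        df["experiment_id"] = experiment_id if experiment_id is not None else path.stem
    for col in ("log2fc", "p_value"):
        bad = df[~pd.to_numeric(df[col], errors="coerce").notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric {col} for gene {bad.iloc[0]['gene_id']!r}"
            )
        df[col] = pd.to_numeric(df[col])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExpressionRecord(
                gene_id=row.gene_id,
                log2fc=float(row.log2fc),
                p_value=float(row.p_value),
                experiment_id=str(row.experiment_id),
            )
        )
    return out


def write_expression_table(records: Sequence[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(writer="expression") + "\n")
        fh.write("gene_id\tlog2fc\tp_value\texperiment_id\n")
        for r in records:
            # repr round-trips float64 exactly, keeping write->read lossless
            fh.write(f"{r.gene_id}\t{r.log2fc!r}\t{r.p_value!r}\t{r.experiment_id}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set name, description, members...)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError("GMT line needs name, description, >=1 member", path, lineno)
            name = f[0]
            if name in sets:
                raise ValidationError(f"duplicate gene set {name!r} in {path}")
            sets[name] = set(g for g in f[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "cotarget"] + sorted(members)) + "\n")


def read_genotype_panels(path) -> dict[str, GenotypePanel]:
    """Read genotype panels from long-format TSV: gene, genotype, replicate, value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "genotype": str},
                     float_precision="round_trip")
    required = {"gene", "genotype", "replicate", "value"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"panel table must have columns {sorted(required)}, got {list(df.columns)}",
            path,
        )
    panels: dict[str, GenotypePanel] = {}
    for gene, sub in df.groupby("gene", sort=True):
        meas = {
            gt: [float(v) for v in grp.sort_values("replicate")["value"]]
            for gt, grp in sub.groupby("genotype", sort=True)
        }
        panels[str(gene)] = GenotypePanel(gene_id=str(gene), measurements=meas)
    return panels


def write_genotype_panels(panels: Mapping[str, GenotypePanel], path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(writer="genotype_panels") + "\n")
        fh.write("gene\tgenotype\treplicate\tvalue\n")
        for gid in sorted(panels):
            panel = panels[gid]
            for gt in ("WT", "mutA", "mutB", "mutAB"):
                for i, v in enumerate(panel.measurements[gt], start=1):
                    fh.write(f"{gid}\t{gt}\t{i}\t{v!r}\n")
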