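"""Readers, writers and validated containers for every external format the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) throughout the
package; the annotation TSS is a 0-based position. Gene identity is the
uppercased symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its format or an invariant."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: symbol, chromosome, strand and primary TSS.

    ``table`` is indexed by uppercased, unique gene symbols with columns
    ``chrom`` (str), ``strand`` ('+'/'-') and ``tss`` (int >= 0).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "strand", "tss"}
        if not required.issubset(t.columns):
            raise FormatError(f"annotation missing columns {required - set(t.columns)}")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dups}")
        if not t.index.equals(t.index.str.upper()):
            raise FormatError("gene symbols must be uppercased")
        bad = ~t["strand"].isin(["+", "-"])
        if bad.any():
            raise FormatError(f"invalid strand for genes {t.index[bad].tolist()}")
        if (t["tss"] < 0).any():
            raise FormatError("negative TSS")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a TSV with header columns gene, chrom, strand, tss.

    Symbols are uppercased; duplicates (after uppercasing) are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["gene", "chrom", "strand", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.strand not in ("+", "-"):
            raise FormatError(f"{path}:{i}: invalid strand {row.strand!r}")
        try:
            tss = int(row.tss)
        except (TypeError, ValueError):
            raise FormatError(f"{path}:{i}: non-integer tss {row.tss!r}") from None
        if tss < 0:
            raise FormatError(f"{path}:{i}: negative tss")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).values,
            "strand": df["strand"].values,
            "tss": df["tss"].astype(int).values,
        },
        index=pd.Index(df["gene"].str.upper(), name="gene"),
    )
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene symbols after uppercasing: {dups}")
    return GeneAnnotation(out)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    df = ann.table.reset_index()
    df.columns = ["gene", "chrom", "strand", "tss"]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count experiment (2x2 factorial design)
# ---------------------------------------------------------------------------

FACTOR_A = ("ctrl", "kd")    # ARID1A knockdown factor
FACTOR_B = ("veh", "e2")     # estrogen treatment factor


@dataclass(frozen=True)
class CountExperiment:
    """Gene x sample integer counts with a two-factor design.

    ``counts``: DataFrame indexed by gene symbol, columns = sample ids.
    ``design``: DataFrame indexed by sample id with columns ``knockdown``
    (ctrl/kd), ``treatment`` (veh/e2) and ``replicate`` (int).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise FormatError("count columns do not match design sample order")
        if not self.design["knockdown"].isin(FACTOR_A).all():
            raise FormatError(f"knockdown factor must be one of {FACTOR_A}")
        if not self.design["treatment"].isin(FACTOR_B).all():
            raise FormatError(f"treatment factor must be one of {FACTOR_B}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (vals < 0).any():
            raise FormatError("negative counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def cell_labels(self) -> pd.Series:
        """Design-cell label per sample, e.g. 'ctrl:veh'."""
        return self.design["knockdown"] + ":" + self.design["treatment"]

    def subset_genes(self, genes: Iterable[str]) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(genes)], self.design)


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountExperiment:
    """Read a gene x sample count TSV and a sample design TSV.

    The design file needs columns sample, knockdown, treatment, replicate.
    Sample order follows the design file.
    """
    design = pd.read_csv(design_path, sep="\t", comment="#")
    required = ["sample", "knockdown", "treatment", "replicate"]
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise FormatError(f"{design_path}: missing columns {missing}")
    design = design.set_index("sample")

    raw = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    raw.index = raw.index.astype(str).str.upper()

    extra = [s for s in raw.columns if s not in design.index]
    absent = [s for s in design.index if s not in raw.columns]
    if extra or absent:
        raise FormatError(
            f"sample mismatch between counts and design: "
            f"not in design {extra}, not in counts {absent}"
        )
    raw = raw[design.index]  # align order to design
    raw.columns = design.index

    vals = raw.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError(f"{counts_path}: non-numeric count entries")
    if not np.array_equal(vals, np.floor(vals)):
        raise FormatError(f"{counts_path}: non-integer count entries")
    counts = raw.astype(np.int64)
    return CountExperiment(counts, design)


def write_counts(expt: CountExperiment, counts_path: str | Path, design_path: str | Path) -> None:
    expt.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    expt.design.rename_axis("sample").to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSet:
    """Genomic intervals for one mark/replicate: 0-based half-open, sorted.

    ``intervals`` has columns chrom (str), start, end (int), signal (float).
    """

    mark: str
    replicate: int
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end", "signal"}
        if not required.issubset(df.columns):
            raise FormatError(f"peak table missing columns {required - set(df.columns)}")
        if (df["start"] >= df["end"]).any():
            raise FormatError("empty or inverted interval (start >= end)")
        if not np.isfinite(df["signal"]).all() or (df["signal"] < 0).any():
            raise FormatError("peak signal must be finite and >= 0")
        srt = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        if not np.array_equal(srt.index.values, df.index.values):
            raise FormatError("intervals must be sorted by (chrom, start, end)")

    def __len__(self) -> int:
        return len(self.intervals)


def _sorted_peak_frame(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )


def make_peakset(
    mark: str,
    replicate: int,
    chroms: Iterable[str],
    starts: Iterable[int],
    ends: Iterable[int],
    signals: Iterable[float] | None = None,
) -> PeakSet:
    """Assemble a PeakSet from columns, sorting and defaulting signal to 1.0."""
    chroms = list(chroms)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": np.asarray(list(starts), dtype=np.int64),
            "end": np.asarray(list(ends), dtype=np.int64),
            "signal": (
                np.ones(len(chroms)) if signals is None else np.asarray(list(signals), dtype=float)
            ),
        }
    )
    return PeakSet(mark, replicate, _sorted_peak_frame(df))


def read_peaks_bed(path: str | Path, mark: str, replicate: int = 1) -> PeakSet:
    """Read BED3+/narrowPeak: columns beyond 5 ignored, track/browser lines skipped.

    Column 5 (score) is taken as the signal when present and numeric;
    otherwise signal defaults to 1.0.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    signals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            signal = 1.0
            if len(fields) >= 5:
                try:
                    signal = float(fields[4])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from None
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            signals.append(signal)
    return make_peakset(mark, replicate, chroms, starts, ends, signals)


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    df = peaks.intervals
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{peaks.mark}\t{row.signal:g}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; symbols uppercased, sets non-empty."""

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def make_collection(sets: Mapping[str, Iterable[str]]) -> GeneSetCollection:
    return GeneSetCollection(
        {name: frozenset(g.upper() for g in members) for name, members in sets.items()}
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member symbols..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: gene set with no members")
            name = fields[0]
            members = frozenset(g.upper() for g in fields[2:] if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = sorted(collection[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# Enhancer-gene links
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnhancerGeneLinks:
    """Enhancer interval to gene links with a confidence score.

    ``table`` columns: chrom, start, end, gene, score.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"chrom", "start", "end", "gene", "score"}
        if not required.issubset(df.columns):
            raise FormatError(f"links table missing columns {required - set(df.columns)}")
        if (df["start"] >= df["end"]).any():
            raise FormatError("invalid enhancer interval")
        if not np.isfinite(df["score"]).all():
            raise FormatError("non-finite link score")

    def __len__(self) -> int:
        return len(self.table)


def read_links(path: str | Path) -> EnhancerGeneLinks:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "start", "end", "gene", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.copy()
    df["gene"] = df["gene"].astype(str).str.upper()
    return EnhancerGeneLinks(df.reset_index(drop=True))


def write_links(links: EnhancerGeneLinks, path: str | Path) -> None:
    links.table.to_csv(path, sep="\t", index=False)
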