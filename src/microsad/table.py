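"""OTU tables, taxonomy maps, and sample metadata.

The universal input of the pipeline is a count table over (sample, OTU)
pairs, where an OTU (operational taxonomic unit, 16S rRNA sequences
clustered at 97% identity) plays the role of a species. Counts are the
number of sequences assigned to each OTU in each community, so they are
strictly non-negative integers; relative abundances are rejected because
the nonparametric richness estimators downstream need integer singleton
and doubleton frequencies.

Files are plain tab-separated text in the classic community-ecology
layout (OTUs as rows, samples as columns, QIIME-style ``#OTU ID`` header
accepted); an orientation flag covers the transpose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "TaxonomyMap",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "parse_sample_label",
    "SITE_CODES",
    "UNCLASSIFIED",
]

#: The six gut sites: food bolus (F) / mucus layer (M) of the proximal
#: small intestine (S), cecum (C), and distal large intestine (L).
SITE_CODES = ("SF", "SM", "CF", "CM", "LF", "LM")

UNCLASSIFIED = "Unclassified"


class TableParseError(ValueError):
    """Raised when an input file violates the tabular format contract."""


@dataclass(frozen=True)
class SampleMetadata:
    """Host/site structure decoded from a community label such as ``FS1SF``."""

    host_id: str
    compartment: str  # S, C or L
    fraction: str  # F (food bolus) or M (mucus layer)

    @property
    def site(self) -> str:
        return self.compartment + self.fraction


def parse_sample_label(label: str) -> SampleMetadata:
    """Split a community label into host id and gut-site code.

    The site code is the last two characters (compartment then fraction);
    everything before it is the host identifier.

    >>> parse_sample_label("FS1SF")
    SampleMetadata(host_id='FS1', compartment='S', fraction='F')
    """
    site = label[-2:].upper()
    if len(label) < 3 or site not in SITE_CODES:
        raise ValueError(
            f"sample label {label!r} does not end in a valid gut-site code "
            f"(one of {', '.join(SITE_CODES)})"
        )
    return SampleMetadata(host_id=label[:-2], compartment=site[0], fraction=site[1])


class OTUTable:
    """Integer count matrix over ordered (sample, OTU) identifiers.

    Parameters
    ----------
    counts
        ``(n_samples, n_otus)`` array of non-negative integers.
    sample_ids, otu_ids
        Unique ordered labels for rows and columns of ``counts``.
    """

    def __init__(self, counts, sample_ids: Iterable[str], otu_ids: Iterable[str]):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers (relative abundances are not accepted)")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        sample_ids = [str(s) for s in sample_ids]
        otu_ids = [str(o) for o in otu_ids]
        if len(sample_ids) != counts.shape[0] or len(otu_ids) != counts.shape[1]:
            raise ValueError("id lists do not match the counts matrix shape")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(otu_ids)) != len(otu_ids):
            raise ValueError("duplicate OTU ids")
        if counts.size == 0:
            raise ValueError("empty table")
        empty = np.flatnonzero(counts.sum(axis=1) == 0)
        if empty.size:
            raise ValueError(f"empty sample (all-zero counts): {sample_ids[empty[0]]}")
        self.counts = counts.astype(np.int64)
        self.sample_ids = sample_ids
        self.otu_ids = otu_ids

    # -- basic container protocol -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Full count row (including zeros) for one sample."""
        return self.counts[self.sample_ids.index(sample_id)]

    def sample_abundances(self, sample_id: str) -> dict[str, int]:
        """Nonzero ``{otu_id: count}`` mapping for one sample."""
        row = self.sample_counts(sample_id)
        nz = np.flatnonzero(row)
        return {self.otu_ids[i]: int(row[i]) for i in nz}

    def observed_otus(self, sample_id: str) -> set[str]:
        """Presence set (count >= 1) of one sample."""
        row = self.sample_counts(sample_id)
        return {self.otu_ids[i] for i in np.flatnonzero(row)}

    def drop_empty_otus(self) -> "OTUTable":
        """Remove OTU columns with zero total count (read totals conserved)."""
        keep = np.flatnonzero(self.counts.sum(axis=0) > 0)
        return OTUTable(self.counts[:, keep], self.sample_ids, [self.otu_ids[i] for i in keep])

    def to_frame(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame view."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OTUTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"<OTUTable {self.n_samples} samples x {self.n_otus} OTUs>"


@dataclass
class TaxonomyMap:
    """OTU → lineage map; only the phylum (first level) is interpreted.

    Lineage levels are separated by ``;`` and carried opaquely below the
    phylum. OTUs absent from the map fall back to ``Unclassified``.
    """

    lineages: dict[str, str] = field(default_factory=dict)

    def phylum(self, otu_id: str) -> str:
        lineage = self.lineages.get(otu_id)
        if not lineage:
            return UNCLASSIFIED
        first = lineage.split(";")[0].strip()
        return first if first else UNCLASSIFIED

    def __len__(self) -> int:
        return len(self.lineages)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages


# -- readers / writers ------------------------------------------------------------

_HEADER_OTU_ID = re.compile(r"^#\s*OTU[ _]?ID", re.IGNORECASE)


def _parse_cell(text: str, line_no: int, col: str) -> int:
    try:
        value = int(text)
    except ValueError:
        try:
            f = float(text)
        except ValueError:
            raise TableParseError(
                f"line {line_no}, column {col!r}: cell {text!r} is not a number"
            ) from None
        if f != int(f):
            raise TableParseError(
                f"line {line_no}, column {col!r}: non-integer count {text!r}"
            ) from None
        value = int(f)
    if value < 0:
        raise TableParseError(f"line {line_no}, column {col!r}: negative count {text!r}")
    return value


def read_otu_table(path, orientation: str = "otus_as_rows") -> OTUTable:
    """Read a tab-separated OTU count table.

    Lines starting with ``#`` before the header are ignored, except a
    QIIME-style ``#OTU ID`` line, which is accepted as the header. The
    first header cell names the id column; body cells must parse as
    non-negative integers.

    Parameters
    ----------
    path : path-like
    orientation : {"otus_as_rows", "samples_as_rows"}
        Layout of the file; the in-memory table is always samples × OTUs.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    header: list[str] | None = None
    row_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if header is None:
                if line.startswith("#") and not _HEADER_OTU_ID.match(line):
                    continue  # comment before header
                header = line.split("\t")
                if len(header) < 2:
                    raise TableParseError(f"line {line_no}: header needs at least one label column")
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise TableParseError(
                    f"line {line_no}: expected {len(header)} columns, found {len(cells)}"
                )
            row_ids.append(cells[0])
            rows.append(
                [_parse_cell(c, line_no, header[j + 1]) for j, c in enumerate(cells[1:])]
            )
    if header is None or not rows:
        raise TableParseError(f"{path}: empty table")
    col_ids = header[1:]
    counts = np.array(rows, dtype=np.int64)
    if orientation == "otus_as_rows":
        return OTUTable(counts.T, sample_ids=col_ids, otu_ids=row_ids)
    return OTUTable(counts, sample_ids=row_ids, otu_ids=col_ids)


def write_otu_table(table: OTUTable, path, orientation: str = "otus_as_rows") -> None:
    """Write a tab-separated OTU table (``#OTU ID`` header in the default layout)."""
    with open(path, "wt", encoding="utf-8") as fh:
        if orientation == "otus_as_rows":
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
            for j, otu in enumerate(table.otu_ids):
                fh.write(otu + "\t" + "\t".join(str(c) for c in table.counts[:, j]) + "\n")
        elif orientation == "samples_as_rows":
            fh.write("sample\t" + "\t".join(table.otu_ids) + "\n")
            for i, sample in enumerate(table.sample_ids):
                fh.write(sample + "\t" + "\t".join(str(c) for c in table.counts[i]) + "\n")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column tab-separated ``otu_id<TAB>lineage`` map.

    Lineage levels are ``;``-separated with the phylum first, e.g.
    ``Firmicutes;Clostridiales``.
    """
    lineages: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise TableParseError(f"line {line_no}: expected 'otu_id<TAB>lineage'")
            otu_id = parts[0].strip()
            if otu_id in lineages:
                raise TableParseError(f"line {line_no}: duplicate OTU id {otu_id!r}")
            lineages[otu_id] = parts[1].strip()
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap | Mapping[str, str], path) -> None:
    lineages = tax.lineages if isinstance(tax, TaxonomyMap) else dict(tax)
    with open(path, "wt", encoding="utf-8") as fh:
        for otu_id, lineage in lineages.items():
            fh.write(f"{otu_id}\t{lineage}\n")
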