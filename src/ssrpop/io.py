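"""Reading, validation, harmonization and export of SSR genotype tables.

SSR (microsatellite) genotypes are co-dominant: a diploid accession carries
two allele copies per locus, scored as integer fragment sizes in base pairs.
Homozygotes are stored as two identical sizes so that every diploid call
contributes exactly two gene copies; putative triploids may carry three
distinct sizes at a locus. Missing data is an empty call.

Two text layouts are supported:

* wide CSV: ``accession_id,collection,name,country,region,<locus>_1,<locus>_2
  [,<locus>_3]...`` with one row per accession;
* long CSV: ``accession_id,locus,allele`` with one row per allele copy.

A Structure-format export (two rows per individual, one integer column per
locus, missing coded as -9) is provided for interoperability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKENS = {"", "NA", "NaN", "nan", "-9"}

REGIONS = ("NorthEast", "West", "South", "unknown")

#: Broad historical European region for each ISO-like country code.
#: North+East = Nordic/Baltic countries plus Russia, Ukraine and Kyrgyzstan;
#: West = Ireland to the Czech Republic; South = Spain and Italy.
REGION_BY_COUNTRY = {
    **{c: "NorthEast" for c in ("SWE", "NOR", "FIN", "DNK", "EST", "LVA",
                                "LTU", "RUS", "UKR", "KGZ")},
    **{c: "West" for c in ("IRL", "GBR", "FRA", "BEL", "NLD", "CHE",
                           "DEU", "CZE")},
    **{c: "South" for c in ("ESP", "ITA")},
}


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed or validated."""


class HarmonizationError(ValueError):
    """Raised when allele-size harmonization is impossible (no shared data)."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one SSR locus in a marker panel.

    Parameters
    ----------
    name : str
        Unique marker name (e.g. ``CH02c09``).
    expected_ploidy : int
        Nominal number of allele copies per call (2 for diploids).
    """

    name: str
    expected_ploidy: int = 2


@dataclass(frozen=True)
class Accession:
    """Passport record for one accession.

    ``region`` is one of ``NorthEast``, ``West``, ``South`` or ``unknown``
    and, when both region and country are given, must agree with the
    country->region mapping in :data:`REGION_BY_COUNTRY`.
    """

    accession_id: str
    name: str = ""
    collection: str = ""
    country: str | None = None
    region: str | None = None


Call = tuple[int, ...]


def _normalize_call(alleles: list[int], where: str = "") -> Call:
    """Sort a call and duplicate single-entry (homozygote) calls."""
    if any(a <= 0 for a in alleles):
        raise GenotypeParseError(f"non-positive allele size at {where}: {alleles}")
    if len(alleles) > 3:
        raise GenotypeParseError(f"more than 3 alleles at {where}: {alleles}")
    if len(alleles) == 1:
        alleles = alleles * 2
    return tuple(sorted(alleles))


@dataclass
class GenotypeTable:
    """Accessions x loci table of SSR calls.

    ``calls[i][l]`` is the sorted tuple of allele sizes of accession ``i``
    at locus ``l``: empty (missing), length 2 (diploid; homozygotes are two
    identical sizes) or length 3 (triploid call).
    """

    loci: list[LocusDef]
    accessions: list[Accession]
    calls: list[list[Call]]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {a.accession_id: i for i, a in enumerate(self.accessions)}
        self.validate()

    # -- basic introspection -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    def call(self, accession_id: str, locus: str) -> Call:
        return self.calls[self._index[accession_id]][self.locus_names.index(locus)]

    def missing_count(self, accession_id: str) -> int:
        """Number of loci without a call for this accession."""
        return sum(1 for c in self.calls[self._index[accession_id]] if not c)

    def validate(self) -> None:
        ids = self.accession_ids
        if len(set(ids)) != len(ids):
            raise GenotypeParseError("duplicate accession_id in table")
        names = self.locus_names
        if len(set(names)) != len(names):
            raise GenotypeParseError("duplicate locus name in panel")
        for acc in self.accessions:
            if acc.region is not None and acc.region not in REGIONS:
                raise GenotypeParseError(
                    f"unknown region {acc.region!r} for {acc.accession_id}")
            if (acc.region not in (None, "unknown") and acc.country
                    and acc.country in REGION_BY_COUNTRY
                    and REGION_BY_COUNTRY[acc.country] != acc.region):
                raise GenotypeParseError(
                    f"region {acc.region!r} inconsistent with country "
                    f"{acc.country!r} for {acc.accession_id}")
        for i, row in enumerate(self.calls):
            if len(row) != self.n_loci:
                raise GenotypeParseError(f"row {ids[i]} has {len(row)} calls, "
                                         f"expected {self.n_loci}")
            for l, call in enumerate(row):
                if len(call) not in (0, 2, 3):
                    raise GenotypeParseError(
                        f"call {call} at ({ids[i]}, {names[l]}) has "
                        f"{len(call)} alleles; expected 0, 2 or 3")
                if any(a <= 0 for a in call) or tuple(sorted(call)) != call:
                    raise GenotypeParseError(
                        f"invalid call {call} at ({ids[i]}, {names[l]})")

    # -- array views ---------------------------------------------------------

    def diploid_matrix(self) -> np.ndarray:
        """(n, L, 2) int array of diploid calls; missing/triploid cells -> -1.

        Triploid calls are masked (treated as unscored) so that callers can
        compare triploid accessions on their diploid loci only.
        """
        out = np.full((self.n_accessions, self.n_loci, 2), -1, dtype=np.int64)
        for i, row in enumerate(self.calls):
            for l, call in enumerate(row):
                if len(call) == 2:
                    out[i, l, :] = call
        return out

    def triploid_locus_counts(self) -> np.ndarray:
        """Per accession, the number of loci showing 3 distinct alleles."""
        return np.array(
            [sum(1 for c in row if len(c) == 3 and len(set(c)) == 3)
             for row in self.calls])

    # -- subsetting ----------------------------------------------------------

    def subset(self, accession_ids: list[str]) -> "GenotypeTable":
        """New table restricted to the given accessions (order preserved)."""
        idx = [self._index[a] for a in accession_ids]
        return GenotypeTable(
            loci=list(self.loci),
            accessions=[self.accessions[i] for i in idx],
            calls=[list(self.calls[i]) for i in idx],
        )

    def with_calls(self, calls: list[list[Call]]) -> "GenotypeTable":
        return GenotypeTable(loci=list(self.loci),
                             accessions=list(self.accessions), calls=calls)

    # -- wide/long dataframes ------------------------------------------------

    def to_wide_frame(self) -> pd.DataFrame:
        has_tri = [any(len(row[l]) == 3 for row in self.calls)
                   for l in range(self.n_loci)]
        records = []
        for acc, row in zip(self.accessions, self.calls):
            rec = {
                "accession_id": acc.accession_id,
                "collection": acc.collection,
                "name": acc.name,
                "country": acc.country or "",
                "region": acc.region or "",
            }
            for l, locus in enumerate(self.locus_names):
                call = row[l]
                rec[f"{locus}_1"] = call[0] if len(call) > 0 else ""
                rec[f"{locus}_2"] = call[1] if len(call) > 1 else ""
                if has_tri[l]:
                    rec[f"{locus}_3"] = call[2] if len(call) > 2 else ""
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for acc, row in zip(self.accessions, self.calls):
            for locus, call in zip(self.locus_names, row):
                for a in call:
                    rows.append((acc.accession_id, locus, a))
        return pd.DataFrame(rows, columns=["accession_id", "locus", "allele"])

    def write_csv(self, path, format: str = "wide_csv") -> None:
        if format == "wide_csv":
            self.to_wide_frame().to_csv(path, index=False)
        elif format == "long_csv":
            self.to_long_frame().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown format {format!r}")


META_COLUMNS = ("accession_id", "collection", "name", "country", "region")


def _parse_allele(token, where: str) -> int | None:
    s = str(token).strip()
    if s in MISSING_TOKENS:
        return None
    try:
        f = float(s)
        i = int(f)
        if f != i:
            raise ValueError
        return i
    except ValueError:
        raise GenotypeParseError(f"cannot parse allele {token!r} at {where}") from None


def _table_from_wide(df: pd.DataFrame) -> GenotypeTable:
    locus_order: list[str] = []
    locus_cols: dict[str, list[str]] = {}
    for col in df.columns:
        if col in META_COLUMNS:
            continue
        if "_" not in col:
            raise GenotypeParseError(f"unrecognized column {col!r}")
        locus, suffix = col.rsplit("_", 1)
        if suffix not in ("1", "2", "3"):
            raise GenotypeParseError(f"unrecognized column {col!r}")
        if locus not in locus_cols:
            locus_cols[locus] = []
            locus_order.append(locus)
        locus_cols[locus].append(col)
    if not locus_order:
        raise GenotypeParseError("no locus columns found in wide table")

    accessions, calls = [], []
    for _, row in df.iterrows():
        acc_id = str(row["accession_id"]).strip()
        accessions.append(Accession(
            accession_id=acc_id,
            name=str(row.get("name", "") or ""),
            collection=str(row.get("collection", "") or ""),
            country=(str(row["country"]).strip() or None)
                    if "country" in df.columns and pd.notna(row["country"]) else None,
            region=(str(row["region"]).strip() or None)
                   if "region" in df.columns and pd.notna(row["region"]) else None,
        ))
        acc_calls = []
        for locus in locus_order:
            alleles = []
            for col in locus_cols[locus]:
                val = row[col] if pd.notna(row[col]) else ""
                a = _parse_allele(val, f"({acc_id}, {locus})")
                if a is not None:
                    alleles.append(a)
            acc_calls.append(_normalize_call(alleles, f"({acc_id}, {locus})")
                             if alleles else ())
        calls.append(acc_calls)
    return GenotypeTable(loci=[LocusDef(n) for n in locus_order],
                         accessions=accessions, calls=calls)


def _table_from_long(df: pd.DataFrame) -> GenotypeTable:
    for col in ("accession_id", "locus", "allele"):
        if col not in df.columns:
            raise GenotypeParseError(f"long table is missing column {col!r}")
    loci = list(dict.fromkeys(df["locus"].astype(str)))
    acc_ids = list(dict.fromkeys(df["accession_id"].astype(str)))
    by_cell: dict[tuple[str, str], list[int]] = {}
    for _, row in df.iterrows():
        a = _parse_allele(row["allele"], f"({row['accession_id']}, {row['locus']})")
        if a is not None:
            by_cell.setdefault((str(row["accession_id"]), str(row["locus"])), []).append(a)
    calls = [[_normalize_call(by_cell[(i, l)], f"({i}, {l})")
              if (i, l) in by_cell else () for l in loci] for i in acc_ids]
    return GenotypeTable(loci=[LocusDef(n) for n in loci],
                         accessions=[Accession(i) for i in acc_ids], calls=calls)


def read_genotype_table(path, format: str = "wide_csv") -> GenotypeTable:
    """Read and validate a genotype table.

    Parameters
    ----------
    path : str or Path
        CSV file to read.
    format : {"wide_csv", "long_csv"}
        Input layout (see module docstring).

    Returns
    -------
    GenotypeTable
        Validated table; homozygotes are normalized to two identical sizes
        and every call is sorted ascending.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if format == "wide_csv":
        return _table_from_wide(df)
    if format == "long_csv":
        return _table_from_long(df)
    raise ValueError(f"unknown format {format!r}")


# -- Structure-format export ------------------------------------------------

def write_structure_file(table: GenotypeTable, path, diploids_only: bool = False) -> None:
    """Write a Structure-format text file (two rows per individual).

    One integer column per locus; missing is coded ``-9``. The format is
    strictly diploid: accessions carrying a 3-allele call raise an error
    unless ``diploids_only`` is set, in which case they are dropped.
    """
    lines = [" ".join(["id"] + table.locus_names)]
    for acc, row in zip(table.accessions, table.calls):
        if any(len(c) == 3 for c in row):
            if diploids_only:
                continue
            raise ValueError(
                f"accession {acc.accession_id} has a triploid call; "
                "Structure format is strictly diploid (use diploids_only=True)")
        for copy in (0, 1):
            vals = [str(c[copy]) if c else "-9" for c in row]
            lines.append(" ".join([acc.accession_id] + vals))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_structure_file(path) -> GenotypeTable:
    """Parse a file produced by :func:`write_structure_file`."""
    with open(path) as fh:
        header = fh.readline().split()
        loci = header[1:]
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) % 2:
        raise GenotypeParseError("odd number of data rows in Structure file")
    accessions, calls = [], []
    for r1, r2 in zip(rows[::2], rows[1::2]):
        if r1[0] != r2[0]:
            raise GenotypeParseError(f"row pair mismatch: {r1[0]} vs {r2[0]}")
        accessions.append(Accession(r1[0]))
        acc_calls = []
        for a, b in zip(r1[1:], r2[1:]):
            if a == "-9" or b == "-9":
                acc_calls.append(())
            else:
                acc_calls.append(tuple(sorted((int(a), int(b)))))
        calls.append(acc_calls)
    return GenotypeTable(loci=[LocusDef(n) for n in loci],
                         accessions=accessions, calls=calls)


# -- cross-laboratory harmonization -----------------------------------------

def harmonize_allele_sizes(
    reference: GenotypeTable,
    other: GenotypeTable,
    shared_ids: list[str] | None = None,
) -> tuple[dict[str, int], GenotypeTable, pd.DataFrame]:
    """Align allele sizes of ``other`` onto the sizing of ``reference``.

    Fragment-size offsets between genotyping platforms are integer and
    constant per locus, so the per-locus offset is estimated as the *mode*
    of the pairwise size differences (reference minus other) over all
    matched allele pairs of accessions scored in both tables. The modal
    offset is added to every call of ``other`` at that locus; loci whose
    observed differences are not all equal are additionally flagged
    ``consistent=False`` in the report for manual review.

    Returns
    -------
    offsets : dict locus -> int
    adjusted : GenotypeTable
        Copy of ``other`` with offsets applied.
    report : DataFrame
        One row per shared locus: ``offset, n_pairs, consistent, applied``.
    """
    if shared_ids is None:
        shared_ids = sorted(set(reference.accession_ids) & set(other.accession_ids))
    shared_loci = [l for l in other.locus_names if l in reference.locus_names]

    offsets: dict[str, int] = {}
    report_rows = []
    any_shared_scored = False
    for locus in shared_loci:
        diffs: list[int] = []
        for acc in shared_ids:
            ref_call = reference.call(acc, locus)
            oth_call = other.call(acc, locus)
            if len(ref_call) == len(oth_call) and ref_call:
                diffs.extend(r - o for r, o in zip(ref_call, oth_call))
        if diffs:
            any_shared_scored = True
            counts = Counter(diffs)
            top = max(counts.values())
            offset = min(d for d, c in counts.items() if c == top)
            consistent = len(counts) == 1
            offsets[locus] = offset
            report_rows.append((locus, offset, len(diffs), consistent, True))
        else:
            report_rows.append((locus, 0, 0, False, False))
    if not any_shared_scored:
        raise HarmonizationError(
            "no shared accession is scored in both tables at any locus")

    new_calls = []
    for row in other.calls:
        new_row = []
        for l, call in enumerate(row):
            off = offsets.get(other.locus_names[l], 0)
            new_row.append(tuple(sorted(a + off for a in call)))
        new_calls.append(new_row)
    adjusted = other.with_calls(new_calls)
    report = pd.DataFrame(report_rows,
                          columns=["locus", "offset", "n_pairs",
                                   "consistent", "applied"])
    return offsets, adjusted, report
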