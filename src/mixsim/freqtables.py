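"""Allele-frequency tables for STR loci: I/O, validation and quality control.

A :class:`FrequencyTable` holds one group's per-locus allele-frequency
distribution together with the number of sampled donors.  Published tables of
this kind (aggregate surveys, the FBI expanded dataset) arrive as "wide" CSV
files — allele labels down the first column, one column per locus — or as
tidy "long" files with ``locus, allele, frequency`` rows.  Both dialects are
supported and round-trip.

Quality control mirrors the filtering ladder applied to published data before
any mixture simulation: completeness over the 13 original core CODIS loci,
and per-locus frequency sums within [0.99, 1.01].  QC *filters*, it never
repairs: renormalisation is only available behind an explicit call intended
for synthetic workflows.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("mixsim")

#: The 13 original core CODIS short-tandem-repeat loci.
CODIS13: frozenset[str] = frozenset(
    {
        "CSF1PO",
        "D3S1358",
        "D5S818",
        "D7S820",
        "D8S1179",
        "D13S317",
        "D16S539",
        "D18S51",
        "D21S11",
        "FGA",
        "TH01",
        "TPOX",
        "vWA",
    }
)

#: Donor count assumed when a table carries no "N" row.  Pairwise F_ST needs a
#: sample size and published tables do not always report one.
DEFAULT_SAMPLE_SIZE = 200


class FrequencyTableError(ValueError):
    """Malformed or invalid frequency-table input."""


@dataclass(frozen=True)
class FrequencyTable:
    """One group's per-locus allele-frequency distribution.

    Parameters
    ----------
    group_id
        Text label for the group.
    sample_size
        Number of donors the frequencies were estimated from (used by the
        Weir–Cockerham F_ST estimator).
    loci
        Mapping ``locus name -> {allele label -> frequency}``.  Allele labels
        stay text so microvariants like ``"9.3"`` survive untouched.
    """

    group_id: str
    sample_size: int
    loci: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if self.sample_size <= 0:
            raise FrequencyTableError(
                f"{self.group_id}: sample_size must be positive, got {self.sample_size}"
            )
        for locus, freqs in self.loci.items():
            if not freqs:
                raise FrequencyTableError(f"{self.group_id}/{locus}: locus has no alleles")
            for allele, p in freqs.items():
                if not (0.0 < p <= 1.0) or math.isnan(p):
                    raise FrequencyTableError(
                        f"{self.group_id}/{locus}: frequency of allele {allele!r} "
                        f"must lie in (0, 1], got {p!r}"
                    )

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(self.loci)

    def locus_sums(self) -> dict[str, float]:
        """Per-locus frequency sums (QC diagnostic)."""
        return {locus: float(sum(freqs.values())) for locus, freqs in self.loci.items()}

    def normalized(self) -> "FrequencyTable":
        """Return a copy with every locus rescaled to sum exactly to 1.

        Explicit by design: published tables are filtered, never silently
        repaired.  Intended for synthetic workflows.
        """
        loci = {
            locus: {a: p / s for a, p in freqs.items()}
            for locus, freqs in self.loci.items()
            for s in (sum(freqs.values()),)
        }
        return FrequencyTable(self.group_id, self.sample_size, loci)

    def digest(self) -> str:
        """SHA-256 of a canonical serialisation (source-concordance hook)."""
        payload = json.dumps(
            {
                locus: {a: repr(p) for a, p in sorted(freqs.items())}
                for locus, freqs in sorted(self.loci.items())
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _parse_cell(text: str, *, row: str, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FrequencyTableError(
            f"malformed numeric cell {text!r} at row {row!r}, column {column!r}"
        ) from None


def read_frequency_table(
    path: str | Path,
    dialect: str = "wide",
    *,
    group_id: str | None = None,
    sample_size: int | None = None,
) -> FrequencyTable:
    """Read a frequency table from CSV.

    ``wide``: first column holds allele labels, one column per locus; an
    optional row labelled ``N`` carries per-table sample size (first non-empty
    cell is used).  Empty cells mean the allele is absent at that locus.

    ``long``: columns ``locus, allele, frequency``; metadata may precede the
    header as ``# key: value`` comment lines (``group_id``, ``sample_size``).

    When no sample size is found, :data:`DEFAULT_SAMPLE_SIZE` is applied with
    a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    gid = group_id if group_id is not None else path.stem
    if dialect == "wide":
        return _read_wide(text, gid, sample_size)
    if dialect == "long":
        return _read_long(text, gid, sample_size)
    raise ValueError(f"unknown dialect {dialect!r}")


def _apply_default_n(gid: str, n: int | None) -> int:
    if n is None:
        logger.warning(
            "%s: no sample size found; defaulting to N=%d", gid, DEFAULT_SAMPLE_SIZE
        )
        return DEFAULT_SAMPLE_SIZE
    return n


def _read_wide(text: str, gid: str, sample_size: int | None) -> FrequencyTable:
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise FrequencyTableError(f"{gid}: empty file")
    header = rows[0]
    locus_names = [c.strip() for c in header[1:]]
    loci: dict[str, dict[str, float]] = {name: {} for name in locus_names}
    n_row: int | None = None
    seen_labels: set[str] = set()
    for row in rows[1:]:
        label = row[0].strip()
        if label.upper() == "N":
            for cell in row[1:]:
                if cell.strip():
                    n_row = int(_parse_cell(cell, row="N", column="(first filled)"))
                    break
            continue
        if label in seen_labels:
            raise FrequencyTableError(f"{gid}: duplicate allele label {label!r}")
        seen_labels.add(label)
        for locus, cell in zip(locus_names, row[1:]):
            if cell.strip():
                loci[locus][label] = _parse_cell(cell, row=label, column=locus)
    loci = {name: freqs for name, freqs in loci.items() if freqs}
    n = sample_size if sample_size is not None else n_row
    return FrequencyTable(gid, _apply_default_n(gid, n), loci)


def _read_long(text: str, gid: str, sample_size: int | None) -> FrequencyTable:
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    rows = list(csv.DictReader(io.StringIO("\n".join(body_lines))))
    loci: dict[str, dict[str, float]] = {}
    for row in rows:
        locus = row["locus"].strip()
        allele = row["allele"].strip()
        freqs = loci.setdefault(locus, {})
        if allele in freqs:
            raise FrequencyTableError(
                f"{gid}: duplicate allele label {allele!r} within locus {locus!r}"
            )
        freqs[allele] = _parse_cell(row["frequency"], row=allele, column=locus)
    if "group_id" in meta:
        gid = meta["group_id"]
    n = sample_size
    if n is None and "sample_size" in meta:
        n = int(meta["sample_size"])
    return FrequencyTable(gid, _apply_default_n(gid, n), loci)


def write_frequency_table(
    table: FrequencyTable, path: str | Path, dialect: str = "wide"
) -> None:
    """Write a table in either CSV dialect; frequencies keep full precision
    (``repr``) so read/write round-trips exactly."""
    path = Path(path)
    if dialect == "wide":
        locus_names = list(table.loci)
        labels = sorted(
            {a for freqs in table.loci.values() for a in freqs},
            key=lambda s: (_label_sort_key(s), s),
        )
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["Allele", *locus_names])
            for label in labels:
                w.writerow(
                    [label]
                    + [
                        repr(table.loci[l][label]) if label in table.loci[l] else ""
                        for l in locus_names
                    ]
                )
            w.writerow(["N", *([str(table.sample_size)] * len(locus_names))])
    elif dialect == "long":
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write(f"# group_id: {table.group_id}\n")
            fh.write(f"# sample_size: {table.sample_size}\n")
            w = csv.writer(fh)
            w.writerow(["locus", "allele", "frequency"])
            for locus, freqs in table.loci.items():
                for allele, p in freqs.items():
                    w.writerow([locus, allele, repr(p)])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _label_sort_key(label: str) -> float:
    try:
        return float(label)
    except ValueError:
        return math.inf


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class QCReport:
    group_id: str
    checks: tuple[QCCheck, ...]

    @property
    def accepted(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "accepted": self.accepted,
            "checks": [
                {"name": c.name, "passed": c.passed, "detail": c.detail}
                for c in self.checks
            ],
        }


def qc_codis_complete(
    table: FrequencyTable, required_loci: Iterable[str] = CODIS13
) -> QCCheck:
    """Pass iff every required locus is present with at least one allele.

    Extra loci beyond the required set are allowed.
    """
    required = set(required_loci)
    if not required:
        raise ValueError("required_loci must be non-empty")
    missing = sorted(required - set(table.loci))
    if missing:
        return QCCheck(
            "codis_complete", False, f"missing loci: {', '.join(missing)}"
        )
    return QCCheck("codis_complete", True, f"all {len(required)} required loci present")


def qc_frequency_sums(
    table: FrequencyTable, lo: float = 0.99, hi: float = 1.01
) -> QCCheck:
    """Pass iff every per-locus frequency sum lies in [lo, hi] (inclusive)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    bad = {
        locus: s for locus, s in table.locus_sums().items() if not (lo <= s <= hi)
    }
    if bad:
        detail = "; ".join(f"{locus}: sum={s:.6g}" for locus, s in sorted(bad.items()))
        return QCCheck("frequency_sums", False, f"out-of-range locus sums: {detail}")
    return QCCheck("frequency_sums", True, f"all locus sums within [{lo}, {hi}]")


def qc_source_concordance(
    table: FrequencyTable, expected_digest: str | None = None
) -> QCCheck:
    """Optional hook standing in for the manual cross-check of aggregate
    tables against their source publications.

    With no expected digest the check is a pass-through; with one, the
    table's canonical SHA-256 must match.
    """
    if expected_digest is None:
        return QCCheck("source_concordance", True, "no expected digest; pass-through")
    actual = table.digest()
    if actual == expected_digest:
        return QCCheck("source_concordance", True, "digest matches source")
    return QCCheck(
        "source_concordance",
        False,
        f"digest mismatch: expected {expected_digest[:12]}…, got {actual[:12]}…",
    )


def run_qc(
    tables: Sequence[FrequencyTable],
    required_loci: Iterable[str] = CODIS13,
    lo: float = 0.99,
    hi: float = 1.01,
    expected_digests: Mapping[str, str] | None = None,
) -> tuple[list[FrequencyTable], list[QCReport]]:
    """Apply the QC ladder to a panel; returns (accepted tables, all reports).

    Input order is preserved in both outputs; one report per input table.
    """
    accepted: list[FrequencyTable] = []
    reports: list[QCReport] = []
    digests = expected_digests or {}
    for table in tables:
        checks = (
            qc_codis_complete(table, required_loci),
            qc_source_concordance(table, digests.get(table.group_id)),
            qc_frequency_sums(table, lo, hi),
        )
        report = QCReport(table.group_id, checks)
        reports.append(report)
        if report.accepted:
            accepted.append(table)
    return accepted, reports


def write_qc_reports(
    reports: Sequence[QCReport], json_path: str | Path, tsv_path: str | Path | None = None
) -> None:
    """Write QC reports as JSON lines, plus an optional TSV summary."""
    with Path(json_path).open("w", encoding="utf-8") as fh:
        for report in reports:
            fh.write(json.dumps(report.to_dict()) + "\n")
    if tsv_path is not None:
        with Path(tsv_path).open("w", encoding="utf-8") as fh:
            fh.write("group_id\taccepted\tfailed_checks\n")
            for report in reports:
                failed = ",".join(c.name for c in report.checks if not c.passed)
                fh.write(f"{report.group_id}\t{report.accepted}\t{failed or '-'}\n")
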