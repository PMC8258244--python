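"""Reading and writing GWAS summary-statistic tables, instrument lists,
exclusion lists and result tables.

All inputs are plain whitespace/tab-delimited text with a header row.
Column names vary wildly across GWAS releases, so every reader takes an
explicit ``column_map`` from canonical field names to the names used in the
file; nothing is auto-sniffed.  Alleles are upper-cased on read (indels are
passed through verbatim), rows violating basic invariants are dropped and
counted, and duplicate rsids keep the first occurrence with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, EmptyInputError, ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .estimators import MrResult

log = logging.getLogger(__name__)

#: canonical field -> whether the column must be present
MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_FIELDS = ("eaf", "pvalue", "n", "n_cases", "n_controls")

RESULT_COLUMNS = ("method", "n_snp", "or", "ci_low", "ci_high", "pvalue",
                  "intercept_pvalue")


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary in one study.

    ``beta`` is the additive effect per copy of ``effect_allele`` on the
    trait scale (log odds ratio for case-control traits); ``eaf`` is the
    effect-allele frequency and may be missing.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None

    def invariant_violation(self) -> str | None:
        """Return a human-readable reason if the record is invalid."""
        if not self.rsid:
            return "empty rsid"
        if not self.effect_allele or not self.other_allele:
            return "empty allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (math.isfinite(self.beta)):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "non-positive se"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "eaf outside [0,1]"
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            return "pvalue outside (0,1]"
        return None


@dataclass(frozen=True)
class InstrumentList:
    """Ordered, unique list of instrument rsids for one exposure."""

    rsids: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.rsids)) != len(self.rsids):
            raise ParameterError("instrument list contains duplicate rsids")

    def __len__(self) -> int:
        return len(self.rsids)

    def __iter__(self):
        return iter(self.rsids)


@dataclass(frozen=True)
class ExclusionList:
    """SNPs to exclude as instruments, each annotated with the confounder
    trait that motivated the exclusion."""

    rsids: tuple[str, ...]
    reasons: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.rsids)) != len(self.rsids):
            raise ParameterError("exclusion list contains duplicate rsids")

    def __len__(self) -> int:
        return len(self.rsids)

    def __contains__(self, rsid: str) -> bool:
        return rsid in set(self.rsids)


class RecordList(list):
    """A list of :class:`GwasRecord` that remembers how many raw rows were
    dropped for invariant violations or duplicate rsids."""

    def __init__(self, records: Iterable[GwasRecord] = (),
                 n_dropped: int = 0,
                 drop_reasons: Counter | None = None,
                 n_duplicates: int = 0) -> None:
        super().__init__(records)
        self.n_dropped = n_dropped
        self.drop_reasons = drop_reasons if drop_reasons is not None else Counter()
        self.n_duplicates = n_duplicates


def _norm_allele(a: object) -> str:
    return str(a).strip().upper()


def _opt_float(value: object) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    if math.isnan(f):
        return None
    return f


def read_gwas(path: str | Path,
              column_map: Mapping[str, str] | None = None) -> RecordList:
    """Read a GWAS summary-statistic table into a :class:`RecordList`.

    Parameters
    ----------
    path:
        Whitespace/tab-delimited file with a header row.
    column_map:
        Mapping from canonical field name (``rsid``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, and optionally ``eaf``,
        ``pvalue``, ``n``, ``n_cases``, ``n_controls``) to the column name
        in the file.  Identity mapping by default.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"summary-statistics file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty summary-statistics file: {path}") from None
    if frame.empty:
        raise EmptyInputError(f"no data rows in summary-statistics file: {path}")

    cmap = dict(column_map or {})
    resolved: dict[str, str] = {}
    for field in MANDATORY_FIELDS + OPTIONAL_FIELDS:
        col = cmap.get(field, field)
        if col in frame.columns:
            resolved[field] = col
        elif field in MANDATORY_FIELDS:
            raise ConfigError(
                f"missing mandatory column '{col}' (field '{field}') in {path}")

    records: list[GwasRecord] = []
    seen: set[str] = set()
    reasons: Counter = Counter()
    n_dup = 0
    for row in frame.itertuples(index=False):
        row = row._asdict()
        get = lambda f: row.get(resolved[f]) if f in resolved else None  # noqa: E731
        beta = _opt_float(get("beta"))
        se = _opt_float(get("se"))
        rec = GwasRecord(
            rsid=str(get("rsid")).strip(),
            effect_allele=_norm_allele(get("effect_allele")),
            other_allele=_norm_allele(get("other_allele")),
            beta=beta if beta is not None else math.nan,
            se=se if se is not None else math.nan,
            eaf=_opt_float(get("eaf")),
            pvalue=_opt_float(get("pvalue")),
            n=_opt_float(get("n")),
            n_cases=_opt_float(get("n_cases")),
            n_controls=_opt_float(get("n_controls")),
        )
        reason = rec.invariant_violation()
        if reason is not None:
            reasons[reason] += 1
            continue
        if rec.rsid in seen:
            n_dup += 1
            continue
        seen.add(rec.rsid)
        records.append(rec)

    n_dropped = sum(reasons.values())
    if n_dropped:
        log.info("read_gwas(%s): dropped %d invalid rows (%s)", path.name,
                 n_dropped, dict(reasons))
    if n_dup:
        log.warning("read_gwas(%s): %d duplicate rsids, kept first occurrence",
                    path.name, n_dup)
    return RecordList(records, n_dropped=n_dropped, drop_reasons=reasons,
                      n_duplicates=n_dup)


def write_gwas(records: Sequence[GwasRecord], path: str | Path) -> None:
    """Write records as a tab-delimited table readable by :func:`read_gwas`."""
    if not records:
        raise EmptyInputError("cannot write an empty set of GWAS records")
    rows = []
    for r in records:
        rows.append({
            "rsid": r.rsid, "effect_allele": r.effect_allele,
            "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
            "se": r.se, "pvalue": r.pvalue, "n": r.n,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def subset_instruments(records: Sequence[GwasRecord],
                       ivs: InstrumentList) -> tuple[RecordList, list[str]]:
    """Restrict ``records`` to the instruments in ``ivs``.

    Returns the matched records in instrument-list order plus the list of
    rsids that could not be found.  An empty intersection is valid.
    """
    by_rsid = {}
    for r in records:
        by_rsid.setdefault(r.rsid, r)  # first wins, mirroring read_gwas
    matched: list[GwasRecord] = []
    unmatched: list[str] = []
    for rsid in ivs:
        rec = by_rsid.get(rsid)
        if rec is None:
            unmatched.append(rsid)
        else:
            matched.append(rec)
    if len(ivs):
        log.info("matched %d/%d instruments (%.1f%%)", len(matched), len(ivs),
                 100.0 * len(matched) / len(ivs))
    return RecordList(matched), unmatched


def read_instruments(path: str | Path, source_label: str | None = None) -> InstrumentList:
    """Read an instrument list: one rsid per line, or the first column of a
    delimited table (a leading ``rsid`` header line is skipped)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"instrument list not found: {path}")
    rsids: list[str] = []
    for line in path.read_text().splitlines():
        token = line.split()[0].strip() if line.split() else ""
        if not token or token.lower() == "rsid":
            continue
        rsids.append(token)
    if not rsids:
        raise EmptyInputError(f"no instruments in {path}")
    return InstrumentList(tuple(rsids), source_label or path.stem)


def read_exclusions(path: str | Path) -> ExclusionList:
    """Read a two-column TSV (rsid, reason) exclusion list; a header line
    starting with ``rsid`` is skipped."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"exclusion list not found: {path}")
    rsids: list[str] = []
    reasons: dict[str, str] = {}
    for line in path.read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if not parts or not parts[0].strip():
            continue
        rsid = parts[0].strip()
        if rsid.lower() == "rsid":
            continue
        if rsid not in reasons:
            rsids.append(rsid)
        reasons[rsid] = parts[1].strip() if len(parts) > 1 else ""
    if not rsids:
        raise EmptyInputError(f"no exclusions in {path}")
    return ExclusionList(tuple(rsids), reasons)


def results_frame(results: Sequence["MrResult"]) -> pd.DataFrame:
    """Tabulate MR results into the fixed report layout."""
    rows = []
    for r in results:
        rows.append({
            "method": r.method,
            "n_snp": int(r.n_snp),
            "or": r.odds_ratio,
            "ci_low": r.or_ci[0],
            "ci_high": r.or_ci[1],
            "pvalue": r.pvalue,
            "intercept_pvalue": r.intercept_pvalue,
        })
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results, path: str | Path) -> None:
    """Write MR results as a tab-delimited table.

    ``results`` may be a sequence of :class:`~summr.estimators.MrResult`
    or an already-tabulated DataFrame with the standard columns.  Odds
    ratios and CI bounds are rendered with four decimals (re-readable
    losslessly at that precision).
    """
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = results_frame(list(results))
    if frame.empty:
        raise EmptyInputError("refusing to write an empty result table")
    frame = frame.copy()
    for col in ("or", "ci_low", "ci_high", "pvalue", "intercept_pvalue"):
        if col in frame.columns:
            frame[col] = frame[col].map(
                lambda v: "NA" if v is None or (isinstance(v, float) and math.isnan(v))
                else f"{v:.4f}")
    frame.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"result table {path} missing columns {missing}")
    return frame


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, entries: Mapping[str, object]) -> None:
    """Write a JSON run-manifest (file hashes, drop counts, match counts,
    seeds).  Keys are sorted so reruns are byte-identical."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
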