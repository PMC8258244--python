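"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs the SNP-outcome effect expressed per copy of the *same*
effect allele used for the SNP-exposure effect.  Studies differ in which
allele they call "effect" and in strand convention, so each SNP is aligned
by (1) direct allele match, (2) swap (sign flip), (3) strand complement,
(4) complement + swap.  Palindromic SNPs (A/T, C/G) are strand-ambiguous:
either dropped outright, or aligned by comparing effect-allele frequencies
to 1-eaf, rejecting SNPs whose frequency is too close to 0.5 to call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import HarmonizationError, ParameterError
from .io import ExclusionList, GwasRecord, InstrumentList, subset_instruments

log = logging.getLogger(__name__)

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_COMP = str.maketrans("ACGT", "TGCA")

#: harmonization modes
FREQUENCY_ALIGN = "frequency-align"
DROP_PALINDROMIC = "drop-palindromic"
_MODES = {FREQUENCY_ALIGN: FREQUENCY_ALIGN, "align": FREQUENCY_ALIGN,
          DROP_PALINDROMIC: DROP_PALINDROMIC, "drop": DROP_PALINDROMIC}


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}."""
    return frozenset((effect_allele.upper(), other_allele.upper())) in _PALINDROMIC


def _complement(allele: str) -> str | None:
    """Reverse complement for pure-ACGT alleles, None otherwise (indels)."""
    a = allele.upper()
    if not a or set(a) - set("ACGT"):
        return None
    return a.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HarmonizedEntry:
    """One SNP aligned across the two studies: gamma is the SNP-exposure
    effect, Gamma the SNP-outcome effect (log-OR), both per copy of the
    exposure study's effect allele."""

    rsid: str
    gamma: float
    sigma_x: float
    Gamma: float
    sigma_y: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    palindromic: bool


@dataclass(frozen=True)
class Rejection:
    rsid: str
    reason: str


def harmonize_pair(exposure: GwasRecord, outcome: GwasRecord,
                   mode: str = FREQUENCY_ALIGN,
                   ambiguity_threshold: float = 0.42) -> HarmonizedEntry | Rejection:
    """Align one outcome record to the exposure record's effect allele.

    Returns a :class:`HarmonizedEntry` or a :class:`Rejection` carrying the
    reason (``palindromic``, ``palindromic: missing eaf``,
    ``palindromic: ambiguous frequency``, ``allele mismatch``).
    """
    if exposure.rsid != outcome.rsid:
        raise ParameterError(
            f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")
    mode = _MODES.get(mode)
    if mode is None:
        raise ParameterError(f"unknown harmonization mode: {mode!r}")
    if not (0 < ambiguity_threshold <= 0.5):
        raise ParameterError("ambiguity_threshold must lie in (0, 0.5]")

    ea_x, oa_x = exposure.effect_allele.upper(), exposure.other_allele.upper()
    ea_y, oa_y = outcome.effect_allele.upper(), outcome.other_allele.upper()
    pal = is_palindromic(ea_x, oa_x)

    def entry(Gamma: float, eaf_out: float | None) -> HarmonizedEntry:
        return HarmonizedEntry(exposure.rsid, exposure.beta, exposure.se,
                               Gamma, outcome.se, exposure.eaf, eaf_out, pal)

    def flipped(eaf):
        return None if eaf is None else 1.0 - eaf

    if pal:
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return Rejection(exposure.rsid, "allele mismatch")
        if mode == DROP_PALINDROMIC:
            return Rejection(exposure.rsid, "palindromic")
        if exposure.eaf is None or outcome.eaf is None:
            return Rejection(exposure.rsid, "palindromic: missing eaf")
        # frequencies near 0.5 cannot disambiguate strand
        lo, hi = ambiguity_threshold, 1.0 - ambiguity_threshold
        if lo <= exposure.eaf <= hi or lo <= outcome.eaf <= hi:
            return Rejection(exposure.rsid, "palindromic: ambiguous frequency")
        # letter-based orientation first, then frequency concordance
        Gamma, eaf_out = outcome.beta, outcome.eaf
        if ea_y == oa_x:  # swapped labelling
            Gamma, eaf_out = -Gamma, flipped(eaf_out)
        if (exposure.eaf < 0.5) != (eaf_out < 0.5):  # opposite strand
            Gamma, eaf_out = -Gamma, flipped(eaf_out)
        return entry(Gamma, eaf_out)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return entry(outcome.beta, outcome.eaf)
    if (ea_y, oa_y) == (oa_x, ea_x):
        return entry(-outcome.beta, flipped(outcome.eaf))
    cea, coa = _complement(ea_y), _complement(oa_y)
    if cea is not None and coa is not None:
        if (cea, coa) == (ea_x, oa_x):
            return entry(outcome.beta, outcome.eaf)
        if (cea, coa) == (oa_x, ea_x):
            return entry(-outcome.beta, flipped(outcome.eaf))
    return Rejection(exposure.rsid, "allele mismatch")


_COLUMNS = ["rsid", "gamma", "sigma_x", "Gamma", "sigma_y", "eaf_exposure",
            "eaf_outcome", "palindromic", "excluded", "exclusion_reason"]


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP exposure/outcome effects -- the unit every estimator
    consumes.  Excluded SNPs stay in the table (flagged) but contribute to
    no estimate."""

    table: pd.DataFrame
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def active(self) -> pd.DataFrame:
        return self.table.loc[~self.table["excluded"]]

    @property
    def n_active(self) -> int:
        return int((~self.table["excluded"]).sum())

    @property
    def n_total(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, sigma_x, Gamma, sigma_y) over active SNPs."""
        a = self.active
        return (a["gamma"].to_numpy(float), a["sigma_x"].to_numpy(float),
                a["Gamma"].to_numpy(float), a["sigma_y"].to_numpy(float))

    def rsids(self) -> list[str]:
        return list(self.active["rsid"])

    def without(self, rsid: str) -> "HarmonizedInstrumentSet":
        """Copy of the set with one SNP removed (leave-one-out helper)."""
        return HarmonizedInstrumentSet(
            self.table.loc[self.table["rsid"] != rsid].reset_index(drop=True))

    def restrict(self, rsids: Sequence[str]) -> "HarmonizedInstrumentSet":
        keep = self.table["rsid"].isin(set(rsids))
        return HarmonizedInstrumentSet(self.table.loc[keep].reset_index(drop=True))


def build_set(exposure_records: Sequence[GwasRecord],
              outcome_records: Sequence[GwasRecord],
              ivs: InstrumentList | None = None,
              mode: str = FREQUENCY_ALIGN,
              ambiguity_threshold: float = 0.42) -> HarmonizedInstrumentSet:
    """Subset to instruments (if given), then harmonize SNP by SNP.

    Raises :class:`HarmonizationError` if nothing survives, since no
    estimator could run on an empty set.
    """
    if ivs is not None:
        exposure_records, unmatched = subset_instruments(exposure_records, ivs)
        if unmatched:
            log.info("instruments absent from exposure study: %s", unmatched)
    outcome_by_rsid: dict[str, GwasRecord] = {}
    for r in outcome_records:
        outcome_by_rsid.setdefault(r.rsid, r)

    entries: list[HarmonizedEntry] = []
    rejections: list[Rejection] = []
    for exp in exposure_records:
        out = outcome_by_rsid.get(exp.rsid)
        if out is None:
            rejections.append(Rejection(exp.rsid, "absent from outcome study"))
            continue
        result = harmonize_pair(exp, out, mode=mode,
                                ambiguity_threshold=ambiguity_threshold)
        if isinstance(result, Rejection):
            rejections.append(result)
        else:
            entries.append(result)
    if not entries:
        raise HarmonizationError(
            "no SNP could be harmonized; rejection reasons: "
            + str(sorted({r.reason for r in rejections})))
    table = pd.DataFrame({
        "rsid": [e.rsid for e in entries],
        "gamma": [e.gamma for e in entries],
        "sigma_x": [e.sigma_x for e in entries],
        "Gamma": [e.Gamma for e in entries],
        "sigma_y": [e.sigma_y for e in entries],
        "eaf_exposure": [e.eaf_exposure for e in entries],
        "eaf_outcome": [e.eaf_outcome for e in entries],
        "palindromic": [e.palindromic for e in entries],
        "excluded": False,
        "exclusion_reason": "",
    }, columns=_COLUMNS)
    log.info("harmonized %d SNPs (%d rejected)", len(entries), len(rejections))
    return HarmonizedInstrumentSet(table, rejections)


def apply_exclusions(hset: HarmonizedInstrumentSet,
                     excl: ExclusionList) -> HarmonizedInstrumentSet:
    """Flag confounder-associated SNPs as excluded (they stay in the table
    but contribute to no estimator)."""
    table = hset.table.copy()
    mask = table["rsid"].isin(set(excl.rsids))
    table.loc[mask, "excluded"] = True
    table.loc[mask, "exclusion_reason"] = [
        excl.reasons.get(r, "confounder-associated")
        for r in table.loc[mask, "rsid"]]
    retained = int((~table["excluded"]).sum())
    log.info("confounder exclusion: %d flagged, %d active", int(mask.sum()),
             retained)
    return HarmonizedInstrumentSet(table, list(hset.rejections))
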