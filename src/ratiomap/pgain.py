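"""P-gain statistics, multiple-testing thresholds and variant curation.

The p-gain of a ratio association is the smaller of the two single-trait
p-values divided by the ratio p-value; on the negative-log10 scale used
throughout this is exact arithmetic on the reported statistics and no
re-exponentiation ever occurs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssociationResult
from .datatypes import GenotypeMatrix
from .errors import DataError, DegenerateVariantError, ValidationError
from .preprocess import TestId


@dataclass(frozen=True)
class ThresholdSet:
    """Bonferroni thresholds for the nested test families (neglog10 scale).

    All values are derived from the genome-wide alpha and the family sizes;
    nothing is hand-set.  ``display()`` rounds to one decimal as in the
    published tables; full precision is retained in the fields.
    """

    alpha_gw: float
    m_lipids: int
    m_traits: int
    m_night: int | None
    m_all: int
    p_ref: float
    p_nmr: float
    p_nightratios: float | None
    p_allratios: float
    pgain_single: float
    gw_tests: float
    pgain_allratios_log10: float

    def display(self) -> dict:
        out = {
            "p_ref": round(self.p_ref, 1),
            "p_nmr": round(self.p_nmr, 1),
            "p_allratios": round(self.p_allratios, 1),
            "pgain_allratios_log10": round(self.pgain_allratios_log10, 1),
        }
        if self.p_nightratios is not None:
            out["p_nightratios"] = round(self.p_nightratios, 1)
        return out

    def for_family(self, family: str) -> float:
        table = {
            "five_lipids": self.p_ref,
            "nmr": self.p_nmr,
            "nightratios": self.p_nightratios,
            "all_ratios": self.p_allratios,
        }
        if family not in table or table[family] is None:
            raise ValidationError(f"unknown or unavailable family {family!r}")
        return table[family]


def compute_thresholds(
    alpha_gw: float = 5e-8,
    m_lipids: int = 5,
    m_traits: int = 168,
    m_night: int | None = 249,
    pgain_single: float = 10.0,
    gw_tests: float = 1e6,
) -> ThresholdSet:
    """Thresholds for the five-lipid, trait, suggested-ratio and all-ratio scans.

    ``p_x = -log10(alpha_gw / m_x)`` with ``m_all = m_traits (m_traits+1)/2``
    counting all ratios plus singles; the p-gain threshold is
    ``log10(pgain_single * gw_tests * m_all)``.
    """
    if not (alpha_gw > 0):
        raise ValidationError(f"alpha_gw must be positive, got {alpha_gw!r}")
    for name, m in (("m_lipids", m_lipids), ("m_traits", m_traits)):
        if m < 1:
            raise ValidationError(f"{name} must be >= 1, got {m}")
    if m_night is not None and m_night < 1:
        raise ValidationError(f"m_night must be >= 1, got {m_night}")
    m_all = m_traits * (m_traits + 1) // 2
    return ThresholdSet(
        alpha_gw=alpha_gw,
        m_lipids=m_lipids,
        m_traits=m_traits,
        m_night=m_night,
        m_all=m_all,
        p_ref=-math.log10(alpha_gw / m_lipids),
        p_nmr=-math.log10(alpha_gw / m_traits),
        p_nightratios=None if m_night is None else -math.log10(alpha_gw / m_night),
        p_allratios=-math.log10(alpha_gw / m_all),
        pgain_single=pgain_single,
        gw_tests=gw_tests,
        pgain_allratios_log10=math.log10(pgain_single * gw_tests * m_all),
    )


@dataclass
class PGainRecord:
    """One (variant, ratio) p-gain with its component single-trait results."""

    variant: str
    test: TestId
    neglog10_p_a: float
    neglog10_p_b: float
    neglog10_p_ratio: float
    log10_pgain: float
    significant_ratio: bool
    significant_pgain: bool


def compute_pgain(
    res_a: AssociationResult,
    res_b: AssociationResult,
    res_ratio: AssociationResult,
    thresholds: ThresholdSet,
) -> PGainRecord:
    """Exact neglog10-scale p-gain for one ratio association.

    ``log10_pgain = neglog10_p_ratio - max(neglog10_p_a, neglog10_p_b)``;
    negative values (ratio weaker than the best single trait) are allowed.
    """
    if res_ratio.test is None or res_ratio.test.kind != "ratio":
        raise ValidationError("res_ratio must carry a ratio TestId")
    if not (res_a.variant == res_b.variant == res_ratio.variant):
        raise ValidationError(
            f"variant mismatch: {res_a.variant!r}, {res_b.variant!r}, {res_ratio.variant!r}"
        )
    singles = {res_a.test.trait_a if res_a.test else None, res_b.test.trait_a if res_b.test else None}
    expected = {res_ratio.test.trait_a, res_ratio.test.trait_b}
    if singles != expected:
        raise ValidationError(f"component traits {singles} do not match ratio {expected}")
    gain = res_ratio.neglog10_p - max(res_a.neglog10_p, res_b.neglog10_p)
    return PGainRecord(
        variant=res_ratio.variant,
        test=res_ratio.test,
        neglog10_p_a=res_a.neglog10_p,
        neglog10_p_b=res_b.neglog10_p,
        neglog10_p_ratio=res_ratio.neglog10_p,
        log10_pgain=gain,
        significant_ratio=res_ratio.neglog10_p > thresholds.p_allratios,
        significant_pgain=gain > thresholds.pgain_allratios_log10,
    )


def pair_pgains(results: list[AssociationResult], thresholds: ThresholdSet) -> list[PGainRecord]:
    """Build p-gain records for all ratio results of one scan.

    ``results`` must contain the single-trait results for every trait
    appearing in a ratio (as produced by ``scan_variant`` over an
    ``enumerate_tests`` list).
    """
    singles: dict[tuple[str, str], AssociationResult] = {}
    for r in results:
        if r.test is not None and r.test.kind == "single":
            singles[(r.variant, r.test.trait_a)] = r
    records = []
    for r in results:
        if r.test is None or r.test.kind != "ratio":
            continue
        try:
            a = singles[(r.variant, r.test.trait_a)]
            b = singles[(r.variant, r.test.trait_b)]
        except KeyError as exc:
            raise ValidationError(f"missing single-trait result for {exc.args[0]}") from None
        records.append(compute_pgain(a, b, r, thresholds))
    return records


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors on complete pairs."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 2:
        raise ValidationError("fewer than 2 complete dosage pairs")
    a, b = a[mask], b[mask]
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise DegenerateVariantError("constant dosage vector in ld_r2")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def curate_variants(
    variants: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_max: float = 0.7,
    maf_min: float = 0.01,
    p_min_neglog10: float = 8.0,
) -> pd.DataFrame:
    """Curate lead variants: MAF filter, strongest-model collapse, LD pruning.

    ``variants`` needs columns ``variant`` and ``neglog10_p`` (per-model
    association strength); an optional ``maf`` column overrides the
    genotype-derived minor allele frequency.  Duplicate variant rows
    collapse to the strongest model; greedy pruning walks variants in
    descending strength (ties broken by variant id) and drops any variant
    with r^2 >= ``r2_max`` to an already-kept one.
    """
    required = {"variant", "neglog10_p"}
    if not required <= set(variants.columns):
        raise ValidationError(f"variants table needs columns {sorted(required)}")
    df = variants.copy()
    for v in df["variant"]:
        if v not in geno.data.columns:
            raise DataError(f"no dosages for listed variant {v!r}")
    if "maf" not in df.columns:
        df["maf"] = [geno.minor_allele_frequency(v) for v in df["variant"]]
    df = df[(df["maf"] > maf_min) & (df["neglog10_p"] >= p_min_neglog10)]
    # strongest model per variant
    df = df.sort_values(["neglog10_p", "variant"], ascending=[False, True])
    df = df.drop_duplicates(subset="variant", keep="first")
    kept_rows = []
    kept_dosages: list[np.ndarray] = []
    for _, row in df.iterrows():
        d = geno.dosage(row["variant"])
        if any(ld_r2(d, kd) >= r2_max for kd in kept_dosages):
            continue
        kept_rows.append(row)
        kept_dosages.append(d)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


@dataclass
class LeadSelection:
    """Lead record at one locus plus its family significance flag."""

    lead: object | None
    significant: bool
    lead_pgain: PGainRecord | None = None


def _nlp(record) -> float:
    return record.neglog10_p_ratio if isinstance(record, PGainRecord) else record.neglog10_p


def select_lead(records: list, thresholds: ThresholdSet, family: str) -> LeadSelection:
    """Strongest record at a locus; for ratios also the strongest p-gain.

    The lead is the record with maximal neglog10 p (ties broken by test
    label); the locus is flagged significant iff the lead passes the
    family threshold.  For p-gain records, the maximal-log10_pgain record
    among pgain-significant ones is additionally returned.
    """
    if not records:
        return LeadSelection(lead=None, significant=False)
    lead = max(records, key=lambda r: (_nlp(r), r.test.label if r.test else ""))
    sel = LeadSelection(lead=lead, significant=_nlp(lead) > thresholds.for_family(family))
    pg = [r for r in records if isinstance(r, PGainRecord) and r.significant_pgain]
    if pg:
        sel.lead_pgain = max(pg, key=lambda r: (r.log10_pgain, r.test.label))
    return sel


@dataclass
class DiscoverySummary:
    """Counts of significant loci across the nested test families."""

    n_loci: int
    n_ref: int
    n_nmr: int
    n_ratio: int
    n_pgain: int
    n_new_via_ratios: int
    n_lost_via_ratios: int
    n_powered: int | None = None
    n_replicated: int | None = None

    @staticmethod
    def from_counts(
        n_loci: int,
        n_ref: int,
        n_nmr: int,
        n_ratio: int = 0,
        n_pgain: int = 0,
        n_new_via_ratios: int = 0,
        n_lost_via_ratios: int = 0,
        n_powered: int | None = None,
        n_replicated: int | None = None,
    ) -> "DiscoverySummary":
        return DiscoverySummary(
            n_loci, n_ref, n_nmr, n_ratio, n_pgain,
            n_new_via_ratios, n_lost_via_ratios, n_powered, n_replicated,
        )

    def percentages(self) -> dict:
        """Derived percentages, rounded to one decimal (0.0 on empty denominators)."""

        def pct(num, den):
            return round(100.0 * num / den, 1) if den else 0.0

        out = {
            "replicated_pct": pct(self.n_ref, self.n_loci),
            "nmr_gain_pct": pct(self.n_nmr - self.n_ref, self.n_ref),
            "new_via_ratios_pct": pct(self.n_new_via_ratios, self.n_nmr),
            "pgain_informative_pct": pct(self.n_pgain, self.n_nmr),
        }
        if self.n_powered is not None and self.n_replicated is not None:
            out["replication_rate_pct"] = pct(self.n_replicated, self.n_powered)
        return out


def count_discoveries(flags: pd.DataFrame) -> DiscoverySummary:
    """Summarize per-locus significance flags across families.

    ``flags`` is indexed by locus with boolean columns ``sig_ref``,
    ``sig_nmr``, ``sig_ratio`` and ``sig_pgain`` (p-gain significance is
    counted among NMR-significant loci only).
    """
    required = {"sig_ref", "sig_nmr", "sig_ratio", "sig_pgain"}
    if not required <= set(flags.columns):
        raise ValidationError(f"flags table needs boolean columns {sorted(required)}")
    if flags.index.has_duplicates:
        raise ValidationError("duplicate locus ids in flags table")
    f = flags.astype(bool)
    return DiscoverySummary(
        n_loci=len(f),
        n_ref=int(f["sig_ref"].sum()),
        n_nmr=int(f["sig_nmr"].sum()),
        n_ratio=int(f["sig_ratio"].sum()),
        n_pgain=int((f["sig_nmr"] & f["sig_pgain"]).sum()),
        n_new_via_ratios=int((f["sig_ratio"] & ~f["sig_nmr"]).sum()),
        n_lost_via_ratios=int((f["sig_nmr"] & ~f["sig_ratio"]).sum()),
    )
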