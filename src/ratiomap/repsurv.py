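"""Replication testing, replication power by subsampling, and fixed-horizon
incident-event risk via the Kaplan-Meier product limit."""
from __future__ import annotations

import datetime
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import fit_linear_assoc
from .datatypes import GenotypeMatrix, TraitMatrix
from .errors import DataError, DegenerateColumnError, ValidationError
from .preprocess import BLOM_OFFSET, TestId, phenotype


@dataclass
class ReplicationResult:
    """Replication outcome for one discovered locus."""

    locus: str
    discovery_neglog10_p: float
    replication_neglog10_p: float | None
    threshold_neglog10: float
    replicated: bool
    direction_concordant: bool | None = None
    power: float | None = None
    n_subsamples: int | None = None
    tested: bool = True


def replication_test(
    replication_results: dict,
    discovery_results: dict,
    n_discovered: int,
) -> list[ReplicationResult]:
    """Flag each discovered locus replicated at p < 0.05 / n_discovered.

    Both arguments map locus id -> AssociationResult; a locus missing from
    ``replication_results`` is reported untested rather than failed.  The
    threshold comparison is strict: replication neglog10 p must exceed
    ``-log10(0.05 / n_discovered)``.
    """
    if n_discovered < 1:
        raise ValidationError(f"n_discovered must be >= 1, got {n_discovered}")
    threshold = -math.log10(0.05 / n_discovered)
    out = []
    for locus, disc in discovery_results.items():
        rep = replication_results.get(locus)
        if rep is None:
            out.append(
                ReplicationResult(locus, disc.neglog10_p, None, threshold, False, tested=False)
            )
            continue
        out.append(
            ReplicationResult(
                locus=locus,
                discovery_neglog10_p=disc.neglog10_p,
                replication_neglog10_p=rep.neglog10_p,
                threshold_neglog10=threshold,
                replicated=rep.neglog10_p > threshold,
                direction_concordant=bool(np.sign(rep.beta) == np.sign(disc.beta))
                if disc.beta and rep.beta
                else None,
            )
        )
    return out


def replication_power(
    log_traits: TraitMatrix,
    geno: GenotypeMatrix,
    covariates,
    loci: list[tuple[str, TestId]],
    n_sub: int,
    threshold_neglog10: float,
    n_reps: int = 100,
    seed: int = 0,
    int_offset: float | str = BLOM_OFFSET,
) -> pd.DataFrame:
    """Power to replicate each locus by repeated subsampling of the discovery set.

    Each replicate draws ``n_sub`` samples without replacement (a fresh
    child seed stream per replicate), rebuilds the phenotype on the
    subsample, refits the lead association, and counts how often the
    neglog10 p exceeds the threshold.  Returns a table with ``power`` per
    locus; deterministic given ``seed``.
    """
    n = log_traits.n_samples
    if n_sub > n:
        raise ValidationError(f"n_sub = {n_sub} exceeds cohort size {n}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    streams = rng.spawn(n_reps)
    hits = {locus_id: 0 for locus_id, _ in loci}
    cov_arr = None if covariates is None else np.asarray(covariates, dtype=float)
    for rep_rng in streams:
        idx = rep_rng.choice(n, size=n_sub, replace=False)
        sub_traits = TraitMatrix(log_traits.data.iloc[idx], log_traits.stage)
        sub_cov = None if cov_arr is None else cov_arr[idx]
        for locus_id, test in loci:
            y = phenotype(sub_traits, test, int_offset)
            res = fit_linear_assoc(
                y, geno.dosage(locus_id)[idx], sub_cov, variant=locus_id, test=test
            )
            if res.neglog10_p > threshold_neglog10:
                hits[locus_id] += 1
    return pd.DataFrame(
        {
            "locus": [lid for lid, _ in loci],
            "test": [t.label for _, t in loci],
            "power": [hits[lid] / n_reps for lid, _ in loci],
            "n_subsamples": n_reps,
            "n_sub": n_sub,
        }
    ).set_index("locus")


# ---------------------------------------------------------------------------
# incident events and survival
# ---------------------------------------------------------------------------

def _parse_date(value, sample="?") -> datetime.date | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, datetime.datetime):
        return value.date()
    if isinstance(value, datetime.date):
        return value
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError:
        raise DataError(f"unparseable date {value!r} for sample {sample!r}") from None


def incident_event_flag(event_date, assessment_date, sample="?") -> str:
    """Classify an event as incident / prevalent / none.

    Incident iff the event date is strictly later than the assessment
    date; an event on the assessment day counts as prevalent.
    """
    assessment = _parse_date(assessment_date, sample)
    if assessment is None:
        raise DataError(f"missing assessment date for sample {sample!r}")
    event = _parse_date(event_date, sample)
    if event is None:
        return "none"
    return "incident" if event > assessment else "prevalent"


def outcome_times(outcomes: pd.DataFrame, horizon_years: float):
    """(times, events, prevalent) arrays from an outcome table.

    Times are years from assessment, censored at the horizon; prevalent
    samples are flagged for exclusion by the caller.
    """
    times = np.empty(len(outcomes))
    events = np.zeros(len(outcomes), dtype=bool)
    prevalent = np.zeros(len(outcomes), dtype=bool)
    for i, (sample, row) in enumerate(outcomes.iterrows()):
        flag = incident_event_flag(row["event_date"], row["assessment_date"], sample)
        if flag == "prevalent":
            prevalent[i] = True
            times[i] = 0.0
            continue
        if flag == "incident":
            if "time_years" in outcomes.columns and not pd.isna(row["time_years"]):
                t = float(row["time_years"])
            else:
                delta = _parse_date(row["event_date"], sample) - _parse_date(
                    row["assessment_date"], sample
                )
                t = delta.days / 365.25
            if t <= horizon_years:
                times[i], events[i] = t, True
            else:
                times[i] = horizon_years
        else:
            times[i] = horizon_years
    return times, events, prevalent


def median_split_groups(values, medication, exclusions=None) -> pd.Series:
    """Four groups: {high, low} trait value x {medication, none}.

    The median is computed on included samples only; ties at the median go
    to the low group (high = strictly above median).  Excluded samples get
    a missing label.
    """
    x = np.asarray(values, dtype=float)
    med = np.asarray(medication, dtype=bool)
    keep = ~np.isnan(x)
    if exclusions is not None:
        keep &= ~np.asarray(exclusions, dtype=bool)
    if keep.sum() == 0:
        raise ValidationError("no samples left after exclusions")
    included = x[keep]
    if np.all(included == included[0]):
        raise DegenerateColumnError("constant trait cannot be median-split")
    cut = float(np.median(included))
    labels = np.where(x > cut, "high", "low")
    labels = np.char.add(labels, np.where(med, "_med", "_nomed"))
    out = pd.Series(labels, dtype="object")
    out[~keep] = pd.NA
    return out


@dataclass
class SurvivalEstimate:
    """Fixed-horizon event risk for one group."""

    group: str
    n_at_risk: int
    events: int
    risk: float
    ci95: tuple[float, float]


def km_risk(times, events, horizon: float = 10.0, group: str = "") -> SurvivalEstimate:
    """Kaplan-Meier risk (1 - S) at the horizon with a Greenwood 95% CI.

    Observations beyond the horizon are censored at the horizon; the CI is
    a symmetric normal interval on the risk scale using the Greenwood
    variance of S, clipped to [0, 1].
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValidationError("times and events lengths differ")
    if np.any(t < 0):
        raise ValidationError("negative times")
    if t.size == 0:
        raise ValidationError("no at-risk samples")
    e = e & (t <= horizon)
    t = np.minimum(t, horizon)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n_at_risk = t.size
    surv = 1.0
    greenwood = 0.0
    i = 0
    at_risk = n_at_risk
    while i < t.size:
        j = i
        d = 0
        while j < t.size and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d > 0 and at_risk > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood += d / (at_risk * (at_risk - d))
        at_risk -= j - i
        i = j
    var_s = surv * surv * greenwood
    risk = 1.0 - surv
    half = 1.959963984540054 * math.sqrt(max(var_s, 0.0))
    return SurvivalEstimate(
        group=group,
        n_at_risk=n_at_risk,
        events=int(e.sum()),
        risk=risk,
        ci95=(max(risk - half, 0.0), min(risk + half, 1.0)),
    )


def km_risk_by_group(times, events, groups, horizon: float = 10.0) -> dict[str, SurvivalEstimate]:
    """Per-group fixed-horizon risk; samples with a missing label are skipped."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = pd.Series(groups).reset_index(drop=True)
    out = {}
    for label in sorted(g.dropna().unique()):
        mask = (g == label).to_numpy()
        if mask.sum() == 0:
            continue
        out[str(label)] = km_risk(t[mask], e[mask], horizon, group=str(label))
    return out


def replication_summary(results: list[ReplicationResult], power_threshold: float = 0.8):
    """(n_powered, n_replicated, rate%) among loci with power above threshold."""
    powered = [r for r in results if r.power is not None and r.power > power_threshold]
    replicated = [r for r in powered if r.replicated]
    n_pow, n_rep = len(powered), len(replicated)
    rate = round(100.0 * n_rep / n_pow, 1) if n_pow else 0.0
    return n_pow, n_rep, rate
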