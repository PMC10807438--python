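"""Biolog plate correction, growth scoring, and niche set algebra.

The pipeline turns raw well absorbances into binary "usable carbon source"
calls per culture, then compares monoculture niches with co-culture niches:

* expected niche of a pair  = A ∩ B (sources both partners use alone)
* observed niche O          = sources the co-culture grows on
* niche expansion (printed) = {(A ∪ B) − (A ∩ B)} ∩ O
* niche expansion (extended)= O − (A ∩ B), which additionally captures
  sources neither partner uses alone
* niche overlap index       = |A ∩ B| / |A ∪ B|  (Jaccard)

Both expansion variants are computed; the printed set formula is the
default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecoplate import PLATE_COLUMNS, WATER, context_id, split_context

EXPANSION_VARIANTS = ("printed", "extended")

CLASS_EXPECTED = "expected_equals_observed"
CLASS_EXPANSION = "expansion"
CLASS_OTHER = "contraction_or_other"


def _check_plate_schema(plates: pd.DataFrame) -> None:
    missing = set(PLATE_COLUMNS) - set(plates.columns)
    if missing:
        raise ValueError(f"plate table lacks columns {sorted(missing)}")
    if not np.isfinite(plates["absorbance"]).all():
        raise ValueError("plate table contains non-finite absorbances")


def _with_context(plates: pd.DataFrame) -> pd.DataFrame:
    out = plates.copy()
    partner = out["partner_id"].fillna("") if "partner_id" in out else ""
    out["context"] = [
        context_id(c, p) for c, p in zip(out["culture_id"], partner)
    ]
    return out


def correct_absorbance(plates: pd.DataFrame) -> pd.DataFrame:
    """Blank- and day-0-correct raw plate absorbances.

    Order of operations: (1) clamp raw negatives to zero; (2) subtract the
    mean water-blank absorbance of the same culture context and day;
    (3) for days after day 0, subtract the same well's day-0 value;
    (4) clamp resulting negatives to zero.  Water wells go through the same
    arithmetic so that the blank distribution used for thresholding is on
    the corrected scale.

    Raises ``ValueError`` if any well lacks a day-0 reading or any context
    and day lacks water blanks.
    """
    _check_plate_schema(plates)
    df = _with_context(plates)
    df["absorbance"] = df["absorbance"].clip(lower=0.0)

    water = df[df["source"] == WATER]
    if water.empty:
        raise ValueError("plate table contains no water-blank wells")
    blank_mean = water.groupby(["context", "day"])["absorbance"].mean()

    key = pd.MultiIndex.from_frame(df[["context", "day"]])
    try:
        df["absorbance"] = df["absorbance"].to_numpy() - blank_mean.loc[key].to_numpy()
    except KeyError as exc:
        raise ValueError(f"missing water blanks for context/day {exc}") from exc

    well = ["context", "source", "replicate"]
    day0 = df[df["day"] == 0].set_index(well)["absorbance"]
    if day0.index.has_duplicates:
        raise ValueError("duplicate day-0 records for some wells")
    wkey = pd.MultiIndex.from_frame(df[well])
    try:
        ref = day0.loc[wkey].to_numpy()
    except KeyError:
        missing = set(map(tuple, df[well].itertuples(index=False))) - set(day0.index)
        raise ValueError(f"wells lacking a day-0 record, e.g. {sorted(missing)[:3]}")
    later = (df["day"] != 0).to_numpy()
    vals = df["absorbance"].to_numpy(dtype=float, copy=True)
    vals[later] -= ref[later]
    df["absorbance"] = np.clip(vals, 0.0, None)
    return df[list(PLATE_COLUMNS) + ["context"]]


def score_growth(
    corrected: pd.DataFrame,
    day: int = 7,
    quantile: float = 0.975,
    quantile_method: str = "linear",
    blank_pool: str = "global",
    min_blanks: int = 3,
) -> pd.DataFrame:
    """Binary niche calls per culture from corrected absorbances.

    For each culture x carbon source, the mean corrected value across
    replicates at ``day`` is compared with the 97.5th percentile of the
    corrected water-blank values at that day (a two-tailed 5% criterion);
    the call is 1 iff strictly greater.  ``blank_pool`` chooses whether the
    blank distribution pools water wells across all culture contexts
    ("global", the default, giving a stably estimated percentile) or uses
    only the three blanks of the same context ("context").

    Returns a wide 0/1 frame indexed by culture context.
    """
    if day not in (4, 7):
        raise ValueError("niche calls use day 4 or day 7")
    if blank_pool not in ("global", "context"):
        raise ValueError("blank_pool must be 'global' or 'context'")
    df = corrected if "context" in corrected.columns else _with_context(corrected)
    at_day = df[df["day"] == day]
    if at_day.empty:
        raise ValueError(f"no corrected records at day {day}")
    blanks = at_day[at_day["source"] == WATER]
    cells = at_day[at_day["source"] != WATER]

    if blank_pool == "global":
        pool = blanks["absorbance"].to_numpy()
        if pool.size < min_blanks:
            raise ValueError(
                f"only {pool.size} blank observations; need >= {min_blanks}"
            )
        thresholds = None
        global_thr = float(np.quantile(pool, quantile, method=quantile_method))
    else:
        counts = blanks.groupby("context").size()
        ctxs = cells["context"].unique()
        short = [c for c in ctxs if counts.get(c, 0) < min_blanks]
        if short:
            raise ValueError(
                f"contexts with fewer than {min_blanks} blanks: {short[:3]}"
            )
        thresholds = blanks.groupby("context")["absorbance"].quantile(
            quantile, interpolation=quantile_method
        )
        global_thr = float("nan")

    means = (
        cells.groupby(["context", "source"], sort=False)["absorbance"]
        .mean()
        .unstack("source")
    )
    source_order = [s for s in df["source"].unique() if s != WATER]
    means = means[source_order]
    if thresholds is None:
        calls = (means > global_thr).astype(int)
    else:
        calls = means.gt(thresholds.reindex(means.index), axis=0).astype(int)
    calls.index.name = "culture"
    return calls


def niche_set(calls_row: pd.Series) -> frozenset:
    """Source set of a binary niche-call row."""
    return frozenset(calls_row.index[calls_row.astype(bool)])


def expected_niche(a: frozenset, b: frozenset) -> frozenset:
    """Expected pair niche: sources both partners use in monoculture."""
    return frozenset(a & b)


def niche_expansion(
    a: frozenset, b: frozenset, observed: frozenset, variant: str = "printed"
) -> frozenset:
    """Sources gained in co-culture relative to the expected niche.

    ``printed`` restricts gains to the symmetric difference of the
    monoculture niches ({(A ∪ B) − (A ∩ B)} ∩ O); ``extended`` is
    O − (A ∩ B), which also counts sources neither partner uses alone.
    """
    if variant not in EXPANSION_VARIANTS:
        raise ValueError(f"variant must be one of {EXPANSION_VARIANTS}")
    if variant == "printed":
        return frozenset((a ^ b) & observed)
    return frozenset(observed - (a & b))


def niche_overlap_index(a: frozenset, b: frozenset) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B|; NaN when both niches are empty
    (undefined, to be excluded from correlations)."""
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def classify_pair(
    a: frozenset, b: frozenset, observed: frozenset, variant: str = "printed"
) -> str:
    """Deformation class of a pair from its monoculture and co-culture niches.

    "expected_equals_observed" iff O = A ∩ B; "expansion" iff the expansion
    set (under ``variant``) is nonempty and the expected niche is retained
    (A ∩ B ⊆ O); anything else — in particular loss of expected sources —
    is flagged "contraction_or_other" rather than merged into either class.
    """
    expected = a & b
    if observed == expected:
        return CLASS_EXPECTED
    if expected <= observed and niche_expansion(a, b, observed, variant):
        return CLASS_EXPANSION
    return CLASS_OTHER


def community_emergence(
    community_observed: frozenset, members: list[frozenset]
) -> frozenset:
    """Sources the full community uses that no member uses alone."""
    union: frozenset = frozenset().union(*members) if members else frozenset()
    return frozenset(community_observed - union)


@dataclass(frozen=True)
class PairNicheResult:
    """Niche set algebra for one unordered pair of strains."""

    pair: tuple[str, str]
    expected_set: frozenset
    observed_set: frozenset
    expansion_set_printed: frozenset
    expansion_set_extended: frozenset
    overlap_index: float
    classification: str
    variant: str = "printed"

    @property
    def expansion_count(self) -> int:
        if self.variant == "printed":
            return len(self.expansion_set_printed)
        return len(self.expansion_set_extended)


def pair_niche_results(
    calls: pd.DataFrame, variant: str = "printed"
) -> list[PairNicheResult]:
    """Compute the niche algebra for every pair context present in a
    wide binary call frame (monoculture rows named "Qi", pair rows
    "Qi+Qj")."""
    if variant not in EXPANSION_VARIANTS:
        raise ValueError(f"variant must be one of {EXPANSION_VARIANTS}")
    mono = {c: niche_set(calls.loc[c]) for c in calls.index if "+" not in c}
    results = []
    for ctx in calls.index:
        members = split_context(ctx)
        if len(members) != 2:
            continue
        i, j = members
        if i not in mono or j not in mono:
            raise ValueError(f"pair {ctx} lacks monoculture calls for {i} or {j}")
        a, b = mono[i], mono[j]
        observed = niche_set(calls.loc[ctx])
        results.append(
            PairNicheResult(
                pair=(i, j),
                expected_set=expected_niche(a, b),
                observed_set=observed,
                expansion_set_printed=niche_expansion(a, b, observed, "printed"),
                expansion_set_extended=niche_expansion(a, b, observed, "extended"),
                overlap_index=niche_overlap_index(a, b),
                classification=classify_pair(a, b, observed, variant),
                variant=variant,
            )
        )
    return results


def summarize_deformation(results: list[PairNicheResult]) -> dict:
    """Counts and fractions per deformation class plus the mean number of
    gained sources among expansion pairs."""
    if not results:
        raise ValueError("no pair results to summarize")
    n = len(results)
    counts = {CLASS_EXPECTED: 0, CLASS_EXPANSION: 0, CLASS_OTHER: 0}
    expansion_counts = []
    for r in results:
        counts[r.classification] += 1
        if r.classification == CLASS_EXPANSION:
            expansion_counts.append(r.expansion_count)
    return {
        "n_pairs": n,
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "mean_expansion_sources": (
            float(np.mean(expansion_counts)) if expansion_counts else 0.0
        ),
    }


def pair_results_frame(results: list[PairNicheResult]) -> pd.DataFrame:
    """Tidy per-pair table (one row per unordered pair)."""
    rows = []
    for r in results:
        rows.append(
            {
                "strain_i": r.pair[0],
                "strain_j": r.pair[1],
                "n_expected": len(r.expected_set),
                "n_observed": len(r.observed_set),
                "expansion_count": r.expansion_count,
                "n_expansion_printed": len(r.expansion_set_printed),
                "n_expansion_extended": len(r.expansion_set_extended),
                "overlap_index": r.overlap_index,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)


def monoculture_ids(calls: pd.DataFrame) -> list[str]:
    return [c for c in calls.index if "+" not in c]


def all_pair_ids(strains: list[str]) -> list[str]:
    return [context_id(a, b) for a, b in itertools.combinations(sorted(strains), 2)]
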