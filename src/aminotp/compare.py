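"""Species-level comparison of trophic position.

One-way fixed-effects ANOVA on per-individual TP point estimates, Tukey HSD
on all species pairs, and a compact letter display (Piepho-style
insert-and-absorb): species sharing a letter are not significantly different
at the chosen alpha. Also the ordinary-least-squares regression of TP on
bulk d15N, with marine-baseline individuals excludable because their food
web's basal d15N is unrelated to the terrestrial ones.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError, ValidationError
from .tp import TPEstimate


@dataclass(frozen=True)
class SpeciesSummary:
    mean: float
    sd: float
    n: int
    min: float
    max: float


@dataclass(frozen=True)
class SpeciesComparison:
    """ANOVA + Tukey results across species."""

    species_means: dict[str, SpeciesSummary]
    anova_F: float
    anova_p: float
    letters: dict[str, str]
    alpha: float
    #: Symmetric pairwise Tukey p-value table (species x species).
    pairwise_p: pd.DataFrame
    excluded_species: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of trophic position on bulk d15N."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    excluded_labels: list[str]
    excluded_ids: list[str]


def _groups_from(data) -> dict[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return {
            sp: g["tp_mean"].to_numpy(dtype=float)
            for sp, g in data.groupby("species", sort=True)
        }
    if isinstance(data, Mapping):
        return {sp: np.asarray(v, dtype=float) for sp, v in sorted(data.items())}
    # Fall back: iterable of TPEstimate.
    out: dict[str, list[float]] = {}
    for e in data:
        if not isinstance(e, TPEstimate):
            raise ValidationError(f"cannot group object of type {type(e).__name__}")
        out.setdefault(e.species, []).append(e.tp_mean)
    return {sp: np.asarray(v, dtype=float) for sp, v in sorted(out.items())}


def compact_letter_display(
    names: Sequence[str],
    means: Mapping[str, float],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one group holding every species; each significant pair splits
    any group containing both; subset groups are absorbed. Letters are
    ordered by descending group mean (ties broken alphabetically), so 'a'
    marks the highest-TP group.
    """
    groups: list[set[str]] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if not significant.get((a, b), significant.get((b, a), False)):
                continue
            nxt: list[set[str]] = []
            for g in groups:
                if a in g and b in g:
                    nxt.extend((g - {a}, g - {b}))
                else:
                    nxt.append(g)
            # absorb: drop any group contained in another
            groups = [
                g for k, g in enumerate(nxt)
                if g and not any(g < h or (g == h and k > j) for j, h in enumerate(nxt))
            ]
    def group_key(g: set[str]) -> tuple[float, str]:
        return (-max(means[m] for m in g), min(g))

    groups.sort(key=group_key)
    if len(groups) > len(string.ascii_lowercase):
        raise InferenceError(f"{len(groups)} letter groups exceed the alphabet")
    letters: dict[str, list[str]] = {n: [] for n in names}
    for letter, g in zip(string.ascii_lowercase, groups):
        for member in g:
            letters[member].append(letter)
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def letters_consistent(
    letters: Mapping[str, str], significant: Mapping[tuple[str, str], bool]
) -> bool:
    """True iff species share a letter exactly when their pair is non-significant."""
    names = sorted(letters)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            share = bool(set(letters[a]) & set(letters[b]))
            sig = significant.get((a, b), significant.get((b, a), False))
            if share == sig:
                return False
    return True


def anova_tukey(
    data: Mapping[str, Sequence[float]] | pd.DataFrame | Iterable[TPEstimate],
    *,
    alpha: float = 0.05,
) -> SpeciesComparison:
    """One-way ANOVA across species plus Tukey HSD with letter display.

    `data` may be a species -> TP-values mapping, a DataFrame with
    ``species`` and ``tp_mean`` columns, or TPEstimate records. Species with
    fewer than 2 values are excluded (listed on the result); fewer than 2
    eligible species is an error. With zero within-group variance the F
    statistic is infinite (p = 0) and pairs are significant iff their means
    differ; if all values are identical, F = 0 and p = 1.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    groups = _groups_from(data)
    excluded = sorted(sp for sp, v in groups.items() if len(v) < 2)
    groups = {sp: v for sp, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise InferenceError(
            f"need >= 2 species with >= 2 estimates each; have {len(groups)} "
            f"(excluded: {excluded or 'none'})"
        )
    names = sorted(groups)
    arrays = [groups[sp] for sp in names]
    summaries = {
        sp: SpeciesSummary(
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)),
            n=len(v),
            min=float(v.min()),
            max=float(v.max()),
        )
        for sp, v in groups.items()
    }
    means = {sp: s.mean for sp, s in summaries.items()}

    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in arrays)
    k = len(names)
    if ss_within == 0.0:
        distinct = len({round(m, 12) for m in means.values()}) > 1
        F, p = (math.inf, 0.0) if distinct else (0.0, 1.0)
        pmat = pd.DataFrame(1.0, index=names, columns=names)
        for a in names:
            for b in names:
                if a != b and means[a] != means[b]:
                    pmat.loc[a, b] = 0.0
    else:
        F, p = (float(x) for x in stats.f_oneway(*arrays))
        hsd = stats.tukey_hsd(*arrays)
        pmat = pd.DataFrame(np.asarray(hsd.pvalue), index=names, columns=names)

    significant = {
        (a, b): bool(pmat.loc[a, b] < alpha)
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    letters = compact_letter_display(names, means, significant)
    if not letters_consistent(letters, significant):  # pragma: no cover - construction guarantees this
        raise InferenceError("compact letter display inconsistent with pairwise tests")
    return SpeciesComparison(
        species_means=summaries,
        anova_F=F,
        anova_p=p,
        letters=letters,
        alpha=alpha,
        pairwise_p=pmat,
        excluded_species=excluded,
    )


def comparison_to_records(cmp: SpeciesComparison) -> list[dict]:
    """Species summary rows for CSV output."""
    return [
        {
            "species": sp,
            "n": s.n,
            "tp_mean": s.mean,
            "tp_sd": s.sd,
            "tp_min": s.min,
            "tp_max": s.max,
            "letters": cmp.letters[sp],
        }
        for sp, s in sorted(cmp.species_means.items())
    ]


def bulk_vs_tp_regression(
    table: pd.DataFrame,
    *,
    exclude: Sequence[str] = ("MARINE",),
) -> RegressionResult:
    """OLS of TP (y) on bulk d15N (x), excluding listed food-web classes.

    `table` needs columns ``tp_mean``, ``d15n_bulk``, ``food_web`` and
    optionally ``sample_id``. At least 3 included points are required.
    """
    required = {"tp_mean", "d15n_bulk", "food_web"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"regression table missing column(s): {sorted(missing)}")
    exclude = [str(e) for e in exclude]
    mask = table["food_web"].astype(str).isin(exclude)
    excluded_ids = (
        table.loc[mask, "sample_id"].astype(str).tolist()
        if "sample_id" in table.columns
        else []
    )
    kept = table.loc[~mask]
    n = len(kept)
    if n < 3:
        raise InferenceError(f"regression needs >= 3 included points, have {n}")
    fit = stats.linregress(kept["d15n_bulk"].to_numpy(float), kept["tp_mean"].to_numpy(float))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=n,
        excluded_labels=list(exclude),
        excluded_ids=excluded_ids,
    )
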