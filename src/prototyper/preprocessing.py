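"""Item scoring, exclusion rules, and z-standardization.

Scores the 15 BFI-S-style items to five trait means (reverse-keyed items
flipped first), applies the panel's exclusion rules — more than one missing
item, or intradimensional answer variance more than four times the sample
average — and standardizes trait scores to z-units, optionally against
reference moments from a derivation wave.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .synthetic import ITEMS_PER_TRAIT, N_ITEMS, TRAITS


class KeymapError(ValueError):
    """The item -> trait key map does not cover the inventory."""


class DegenerateSampleError(ValueError):
    """The sample cannot support the requested operation."""


@dataclasses.dataclass(frozen=True)
class Keymap:
    """Assignment of each of the 15 items to a trait and a key direction.

    ``trait_items`` maps trait name -> tuple of 1-based item indices;
    ``reverse_keyed`` lists items whose responses are flipped
    (``levels + 1 - value``) before scoring.
    """

    trait_items: dict[str, tuple[int, ...]]
    reverse_keyed: frozenset[int] = frozenset()
    likert_levels: int = 7

    def __post_init__(self) -> None:
        covered = [i for items in self.trait_items.values() for i in items]
        if sorted(covered) != list(range(1, N_ITEMS + 1)):
            raise KeymapError(
                "keymap must assign each of the 15 items to exactly one trait"
            )
        if set(self.trait_items) != set(TRAITS):
            raise KeymapError(f"keymap must cover the five traits {TRAITS}")
        if any(len(items) != ITEMS_PER_TRAIT for items in self.trait_items.values()):
            raise KeymapError("each trait must have exactly 3 items")
        bad = [i for i in self.reverse_keyed if not 1 <= i <= N_ITEMS]
        if bad:
            raise KeymapError(f"reverse_keyed items out of range: {bad}")


#: Three consecutive items per trait, second item of each trait reversed.
#: The inventory's true key map is not public; this default is arbitrary but
#: matches the synthetic generator's default.
DEFAULT_KEYMAP = Keymap(
    trait_items={
        "neuroticism": (1, 2, 3),
        "extraversion": (4, 5, 6),
        "openness": (7, 8, 9),
        "agreeableness": (10, 11, 12),
        "conscientiousness": (13, 14, 15),
    },
    reverse_keyed=frozenset({2, 5, 8, 11, 14}),
)


def _keyed_responses(items: pd.DataFrame, keymap: Keymap) -> np.ndarray:
    """Return the (n, 15) response matrix with reverse-keyed items flipped."""
    values = items.to_numpy(dtype=float, copy=True)
    if values.shape[1] != N_ITEMS:
        raise KeymapError(f"expected {N_ITEMS} item columns, got {values.shape[1]}")
    for idx in keymap.reverse_keyed:
        col = idx - 1
        values[:, col] = (keymap.likert_levels + 1) - values[:, col]
    return values


def score_traits(items: pd.DataFrame, keymap: Keymap = DEFAULT_KEYMAP) -> pd.DataFrame:
    """Score items to trait means.

    A trait score is the mean of the available keyed items for that trait;
    a trait with all three items missing is missing.
    """
    keyed = _keyed_responses(items, keymap)
    scores = {}
    for trait in TRAITS:
        cols = [i - 1 for i in keymap.trait_items[trait]]
        block = keyed[:, cols]
        scores[trait] = _row_mean(block)
    return pd.DataFrame(scores, index=items.index)


def _row_mean(block: np.ndarray) -> np.ndarray:
    """Row means ignoring NaN, NaN where a row has no observed value."""
    observed = ~np.isnan(block)
    count = observed.sum(axis=1)
    total = np.where(observed, block, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def intradimensional_variance(
    items: pd.DataFrame, keymap: Keymap = DEFAULT_KEYMAP
) -> pd.Series:
    """Per-person mean, over traits, of the within-trait item variance.

    Uses the population variance (denominator = number of available items)
    over each trait's items; traits with fewer than two available items are
    skipped in the mean.  NaN when no trait has two or more available items.
    """
    keyed = _keyed_responses(items, keymap)
    per_trait = np.full((keyed.shape[0], len(TRAITS)), np.nan)
    for t, trait in enumerate(TRAITS):
        cols = [i - 1 for i in keymap.trait_items[trait]]
        block = keyed[:, cols]
        n_avail = np.sum(~np.isnan(block), axis=1)
        mean = _row_mean(block)
        var = _row_mean((block - mean[:, None]) ** 2)
        per_trait[:, t] = np.where(n_avail >= 2, var, np.nan)
    return pd.Series(
        _row_mean(per_trait), index=items.index, name="intradim_variance"
    )


def apply_exclusions(
    items: pd.DataFrame,
    keymap: Keymap = DEFAULT_KEYMAP,
    multiplier: float = 4.0,
) -> pd.DataFrame:
    """Flag persons excluded by the missingness and answer-variance rules.

    A person is excluded when they have more than one missing item, or when
    their intradimensional answer variance is strictly greater than
    ``multiplier`` times the sample average (computed before any exclusion,
    over persons with a computable variance).

    Returns an exclusion report: ``n_missing``, ``intradim_variance``,
    ``excluded``, ``reason`` (comma-joined, empty when retained).
    """
    n_missing = items.isna().sum(axis=1)
    intravar = intradimensional_variance(items, keymap)
    sample_avg = float(intravar.mean())  # skips NaN rows by definition
    too_missing = n_missing > 1
    too_variable = intravar > multiplier * sample_avg
    excluded = too_missing | too_variable.fillna(False)
    if bool(excluded.all()):
        raise DegenerateSampleError("all persons excluded; sample is degenerate")
    reason = pd.Series("", index=items.index, dtype=object)
    reason[too_variable.fillna(False)] = "variance"
    reason[too_missing] = "missing"
    reason[too_missing & too_variable.fillna(False)] = "missing,variance"
    return pd.DataFrame(
        {
            "n_missing": n_missing,
            "intradim_variance": intravar,
            "excluded": excluded,
            "reason": reason,
        }
    )


@dataclasses.dataclass(frozen=True)
class Moments:
    """Per-trait means and SDs used for (de)standardization."""

    mean: pd.Series
    sd: pd.Series


def zstandardize(
    traits: pd.DataFrame, reference: Moments | None = None
) -> tuple[pd.DataFrame, Moments]:
    """Standardize trait scores to mean 0, SD 1 per trait.

    With ``reference`` moments (e.g. from a derivation wave), those are used
    instead of the sample's own; the moments actually applied are returned
    so the transform can be inverted or reused on a test wave.
    """
    cols = list(TRAITS)
    frame = traits[cols]
    if reference is None:
        mean = frame.mean()
        sd = frame.std(ddof=0)
        zero = sd[sd <= 0]
        if len(zero):
            raise DegenerateSampleError(
                f"zero standard deviation for trait(s): {', '.join(zero.index)}"
            )
        reference = Moments(mean=mean, sd=sd)
    z = (frame - reference.mean) / reference.sd
    return z, reference


def destandardize(z: pd.DataFrame, moments: Moments) -> pd.DataFrame:
    """Invert :func:`zstandardize` given the moments it reported."""
    return z[list(TRAITS)] * moments.sd + moments.mean
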