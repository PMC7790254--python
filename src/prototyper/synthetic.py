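"""Synthetic SOEP-like Big Five item data with planted prototype structure.

Generates person x item Likert response tables from a five-component
Gaussian mixture in trait z-space, discretizes traits to 3 items per trait,
injects careless responders and MCAR missingness, and synthesizes criterion
variables with specified population correlations to the traits.  Every
downstream stage of the prototyping pipeline is testable against the planted
ground truth without access to restricted panel data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

TRAITS = (
    "neuroticism",
    "extraversion",
    "openness",
    "agreeableness",
    "conscientiousness",
)
N_TRAITS = 5
ITEMS_PER_TRAIT = 3
N_ITEMS = N_TRAITS * ITEMS_PER_TRAIT
ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))

#: Sign-pattern prototype profiles at +/-0.9 z.  The literature reports only
#: directional patterns for these types, so the magnitude is a modelling
#: choice: 0.9 makes the observed traits approximately unit-variance under
#: the default mixing weights and noise levels (between-component variance
#: ~0.67 + within 0.25 + measurement ~0.11), i.e. the planted profiles are
#: expressed in observed z units.  Signs follow the canonical five-type
#: descriptions: resilient = low N, high everything else; overcontroller =
#: high N, low E/O; undercontroller = low O/A/C; reserved = low N/E/O, high
#: A/C; vulnerable-resilient = above average on all five traits including N.
DEFAULT_PROTOTYPE_MEANS: dict[str, tuple[float, ...]] = {
    "resilient": (-0.9, 0.9, 0.9, 0.9, 0.9),
    "overcontroller": (0.9, -0.9, -0.9, 0.0, 0.0),
    "undercontroller": (0.0, 0.0, -0.9, -0.9, -0.9),
    "reserved": (-0.9, -0.9, -0.9, 0.9, 0.9),
    "vulnerable-resilient": (0.9, 0.9, 0.9, 0.9, 0.9),
}

#: Mixture weights matching the reported prevalence of the five types
#: (resilient 14.4%, overcontroller 17.3%, undercontroller 24.6%,
#: reserved 22.5%, vulnerable-resilient 21.2%).
DEFAULT_MIXING_PROPORTIONS = (0.144, 0.173, 0.246, 0.225, 0.212)


class ConfigurationError(ValueError):
    """Raised when a generator or criterion configuration is invalid."""


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Population model for the synthetic panel.

    Parameters
    ----------
    n_persons:
        Number of simulated respondents.
    prototype_means:
        Mapping prototype name -> 5-vector of trait z-scores (component
        means of the mixture), in trait order ``TRAITS``.
    mixing_proportions:
        Component weights; must sum to 1.
    within_sd:
        Within-component standard deviation in trait z-space (scalar or one
        value per trait).  Default 0.5 keeps components recoverable while
        producing realistic overlap.
    item_noise_sd:
        SD of additive Gaussian noise on each item before rounding, on the
        Likert scale.
    likert_levels:
        Number of response categories (7 for the BFI-S).
    reverse_keyed:
        1-based item indices whose responses are flipped.  The real
        inventory's key map is not public; the default (second item of each
        trait) is an arbitrary but fixed choice.
    missing_rate:
        Per-cell MCAR missingness probability among non-careless persons.
    careless_rate:
        Fraction of persons answering uniformly at random across the scale.
    seed:
        Seed for all randomness; identical config + seed gives identical
        output.
    """

    n_persons: int = 4000
    prototype_means: dict[str, tuple[float, ...]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROTOTYPE_MEANS)
    )
    mixing_proportions: tuple[float, ...] = DEFAULT_MIXING_PROPORTIONS
    within_sd: float | tuple[float, ...] = 0.5
    item_noise_sd: float = 0.5
    likert_levels: int = 7
    reverse_keyed: frozenset[int] = frozenset({2, 5, 8, 11, 14})
    missing_rate: float = 0.0
    careless_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be positive")
        props = np.asarray(self.mixing_proportions, dtype=float)
        if len(props) != len(self.prototype_means):
            raise ConfigurationError(
                "mixing_proportions length must match number of prototypes"
            )
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError("mixing proportions must be >= 0 and sum to 1")
        for name, mu in self.prototype_means.items():
            if len(mu) != N_TRAITS:
                raise ConfigurationError(
                    f"prototype {name!r} mean must have {N_TRAITS} components"
                )
        for rate_name in ("missing_rate", "careless_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{rate_name} must be in [0, 1]")
        sd = np.atleast_1d(np.asarray(self.within_sd, dtype=float))
        if sd.size not in (1, N_TRAITS) or np.any(sd < 0):
            raise ConfigurationError("within_sd must be a scalar or 5 non-negative values")
        if self.item_noise_sd < 0:
            raise ConfigurationError("item_noise_sd must be non-negative")
        if self.likert_levels < 2:
            raise ConfigurationError("likert_levels must be at least 2")
        bad = [i for i in self.reverse_keyed if not 1 <= i <= N_ITEMS]
        if bad:
            raise ConfigurationError(f"reverse_keyed items out of range: {bad}")

    @property
    def prototype_names(self) -> tuple[str, ...]:
        return tuple(self.prototype_means)


@dataclasses.dataclass(frozen=True)
class CriterionSpec:
    """A criterion variable with target population correlations to traits.

    ``trait_correlations`` is the vector of desired Pearson correlations
    between the criterion and the five trait z-scores.  The criterion is a
    linear combination of the traits plus Gaussian noise; feasibility
    (implied R^2 <= 1 under the trait correlation matrix) is checked at
    generation time.
    """

    name: str
    trait_correlations: tuple[float, ...]
    noise: str = "gaussian"

    def __post_init__(self) -> None:
        if len(self.trait_correlations) != N_TRAITS:
            raise ConfigurationError(
                f"criterion {self.name!r} needs {N_TRAITS} trait correlations"
            )
        rho = np.asarray(self.trait_correlations, dtype=float)
        if np.any(np.abs(rho) >= 1):
            raise ConfigurationError(
                f"criterion {self.name!r} correlations must lie in (-1, 1)"
            )
        if self.noise != "gaussian":
            raise ConfigurationError("only Gaussian criterion noise is supported")


def _likert_scale_params(levels: int) -> tuple[float, float]:
    # Affine map z -> Likert: midpoint at the scale center, +/-3 z spanning
    # the full response range.
    midpoint = (1 + levels) / 2.0
    slope = (levels - 1) / 6.0
    return midpoint, slope


def trait_to_items(
    traits: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Map an (n, 5) trait z matrix to an (n, 15) integer Likert matrix."""
    n = traits.shape[0]
    midpoint, slope = _likert_scale_params(config.likert_levels)
    raw = np.repeat(traits, ITEMS_PER_TRAIT, axis=1) * slope + midpoint
    raw += rng.normal(scale=config.item_noise_sd, size=(n, N_ITEMS))
    for idx in config.reverse_keyed:
        raw[:, idx - 1] = (config.likert_levels + 1) - raw[:, idx - 1]
    return np.clip(np.rint(raw), 1, config.likert_levels)


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw persons from the prototype mixture and discretize to items.

    Returns
    -------
    items:
        DataFrame indexed by ``person_id`` with columns ``item_01..item_15``
        of float responses in {1..likert_levels} (floats so that missing
        cells can later be NaN).
    true_labels:
        Series of prototype names, the planted component of each person.
    """
    rng = np.random.default_rng(config.seed)
    names = config.prototype_names
    means = np.asarray([config.prototype_means[name] for name in names], dtype=float)
    components = rng.choice(len(names), size=config.n_persons, p=config.mixing_proportions)
    sd = np.broadcast_to(
        np.atleast_1d(np.asarray(config.within_sd, dtype=float)), (N_TRAITS,)
    )
    traits = means[components] + rng.normal(size=(config.n_persons, N_TRAITS)) * sd
    items = trait_to_items(traits, config, rng)
    person_id = pd.RangeIndex(1, config.n_persons + 1, name="person_id")
    items_df = pd.DataFrame(items, index=person_id, columns=list(ITEM_COLUMNS))
    labels = pd.Series([names[c] for c in components], index=person_id, name="true_label")
    return items_df, labels


def inject_missing_and_careless(
    items: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Overwrite a careless fraction of rows with uniform random answers and
    set MCAR missingness on the remaining cells.

    Returns the perturbed item table and a boolean Series flagging the
    planted careless rows.  Uses a seed offset so that the perturbation does
    not rewind the population draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = items.to_numpy(dtype=float, copy=True)
    n = out.shape[0]
    careless = rng.random(n) < config.careless_rate
    n_careless = int(careless.sum())
    if n_careless:
        out[careless] = rng.integers(
            1, config.likert_levels + 1, size=(n_careless, N_ITEMS)
        ).astype(float)
    if config.missing_rate > 0:
        missing = rng.random(out.shape) < config.missing_rate
        missing[careless] = False
        out[missing] = np.nan
    result = pd.DataFrame(out, index=items.index, columns=items.columns)
    flags = pd.Series(careless, index=items.index, name="careless")
    return result, flags


def generate_criteria(
    traits_z: pd.DataFrame,
    specs: list[CriterionSpec],
    seed: int,
) -> pd.DataFrame:
    """Synthesize criterion variables with target trait correlations.

    Each criterion is ``y = Z w + sigma * e`` with ``w`` solved from the
    target correlation vector rho and the empirical trait correlation matrix
    R (``R w = rho``), so the population correlation vector of y with the
    traits equals rho and Var(y) = 1.  Infeasible targets (implied
    R^2 = rho' R^-1 rho > 1) raise :class:`ConfigurationError`.
    """
    z = traits_z[list(TRAITS)].to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("criterion generation requires complete trait scores")
    corr = np.corrcoef(z, rowvar=False)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out = {}
    for spec in specs:
        rho = np.asarray(spec.trait_correlations, dtype=float)
        weights = np.linalg.solve(corr, rho)
        r_squared = float(rho @ weights)
        if r_squared > 1.0 + 1e-9:
            raise ConfigurationError(
                f"criterion {spec.name!r} infeasible: implied R^2 = {r_squared:.3f} > 1"
            )
        sigma = float(np.sqrt(max(0.0, 1.0 - r_squared)))
        # standardize traits so the weights act on unit-variance columns
        zu = (z - z.mean(axis=0)) / z.std(axis=0)
        out[spec.name] = zu @ weights + sigma * rng.standard_normal(z.shape[0])
    return pd.DataFrame(out, index=traits_z.index)


# -- plain-text round trip ---------------------------------------------------


def write_items_csv(items: pd.DataFrame, path: str | Path) -> None:
    """Write the item table as CSV with empty cells for missing values."""
    items.to_csv(path, float_format="%.0f", na_rep="")


def read_items_csv(path: str | Path) -> pd.DataFrame:
    items = pd.read_csv(path, index_col="person_id")
    return items[list(ITEM_COLUMNS)].astype(float)


def write_truth_sidecar(
    labels: pd.Series, config: GeneratorConfig, path: str | Path
) -> None:
    payload = {
        "true_labels": {str(k): v for k, v in labels.items()},
        "config": {
            "n_persons": config.n_persons,
            "prototype_means": {k: list(v) for k, v in config.prototype_means.items()},
            "mixing_proportions": list(config.mixing_proportions),
            "within_sd": np.asarray(config.within_sd).tolist(),
            "item_noise_sd": config.item_noise_sd,
            "likert_levels": config.likert_levels,
            "reverse_keyed": sorted(config.reverse_keyed),
            "missing_rate": config.missing_rate,
            "careless_rate": config.careless_rate,
            "seed": config.seed,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
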