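"""Prototype labeling, profile similarity, and predictive validity.

Labels cluster centers against literature reference prototypes by Euclidean
distance in Big Five z-space, computes each person's profile similarity D
(Cronbach–Gleser, here the Euclidean distance between z-profiles) to every
prototype, and correlates the inverse similarities and raw traits with
criterion variables.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .synthetic import TRAITS

logger = logging.getLogger(__name__)

#: Sign-pattern reference table (+/-0.6 z) transcribed from prose
#: descriptions of the five canonical types.  Non-canonical: the published
#: literature-average profiles are shown only graphically, so these encode
#: directions, not magnitudes; supply your own table (CSV) for literature
#: matching.  Trait order: neuroticism, extraversion, openness,
#: agreeableness, conscientiousness.
_DEFAULT_REFERENCE_CSV = """\
prototype,neuroticism,extraversion,openness,agreeableness,conscientiousness
resilient,-0.9,0.9,0.9,0.9,0.9
overcontroller,0.9,-0.9,-0.9,0.0,0.0
undercontroller,0.0,0.0,-0.9,-0.9,-0.9
reserved,-0.9,-0.9,-0.9,0.9,0.9
vulnerable-resilient,0.9,0.9,0.9,0.9,0.9
"""


def default_reference_table() -> pd.DataFrame:
    """The shipped sign-pattern reference prototype table."""
    return load_reference_table(io.StringIO(_DEFAULT_REFERENCE_CSV))


def load_reference_table(source) -> pd.DataFrame:
    """Read a reference prototype table (CSV: prototype name + 5 trait
    z-scores) and validate it."""
    table = pd.read_csv(source).set_index("prototype")
    missing = [t for t in TRAITS if t not in table.columns]
    if missing:
        raise ValueError(f"reference table missing trait columns: {missing}")
    table = table[list(TRAITS)].astype(float)
    if len(table) < 2:
        raise ValueError("reference table needs at least two prototypes")
    if table.index.duplicated().any():
        raise ValueError("reference prototype names must be unique")
    return table


def profile_similarity_D(a, b) -> float:
    """Cronbach–Gleser profile similarity D: the Euclidean distance between
    two complete 5-trait z-profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (len(TRAITS),) or b.shape != (len(TRAITS),):
        raise ValueError(f"profiles must be {len(TRAITS)}-vectors")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("profiles must be complete (no missing components)")
    return float(np.linalg.norm(a - b))


@dataclasses.dataclass
class PrototypeLabeling:
    """Cluster -> prototype-name labels with their profile distances."""

    names: dict[int, str]
    distances: dict[int, float]
    conflicts: list[str]
    one_to_one: bool


def label_prototypes(
    centers: np.ndarray,
    reference: pd.DataFrame | None = None,
    one_to_one: bool = False,
) -> PrototypeLabeling:
    """Name clusters by their nearest literature prototype.

    Per cluster, the reference prototype at minimal Euclidean distance D in
    Big Five z-space.  With ``one_to_one`` the assignment minimizes total D
    under a bijection constraint instead; nearest-name conflicts (two
    clusters sharing a nearest prototype, or exact distance ties) are
    reported either way.  Ties resolve to the lexicographically first name.
    """
    if reference is None:
        reference = default_reference_table()
    if len(reference) == 0:
        raise ValueError("reference table is empty")
    centers = np.asarray(centers, dtype=float)
    ref = reference.to_numpy(dtype=float)
    ref_names = list(reference.index)
    d = np.linalg.norm(centers[:, None, :] - ref[None, :, :], axis=2)
    conflicts: list[str] = []
    names: dict[int, str] = {}
    distances: dict[int, float] = {}
    if one_to_one:
        if len(ref_names) < centers.shape[0]:
            raise ValueError("one-to-one labeling needs >= k reference prototypes")
        rows, cols = linear_sum_assignment(d)
        for r, c in zip(rows, cols):
            names[r + 1] = ref_names[c]
            distances[r + 1] = float(d[r, c])
            if ref_names[int(np.argmin(d[r]))] != ref_names[c]:
                conflicts.append(
                    f"cluster {r + 1}: nearest is {ref_names[int(np.argmin(d[r]))]!r} "
                    f"but assigned {ref_names[c]!r} under the bijection"
                )
    else:
        for r in range(centers.shape[0]):
            row = d[r]
            best = float(row.min())
            tied = sorted(ref_names[j] for j in np.flatnonzero(
                np.isclose(row, best, rtol=0.0, atol=1e-12)))
            if len(tied) > 1:
                conflicts.append(
                    f"cluster {r + 1} equidistant to {tied}; chose {tied[0]!r}"
                )
            names[r + 1] = tied[0]
            distances[r + 1] = best
        seen: dict[str, int] = {}
        for cluster, name in names.items():
            if name in seen:
                conflicts.append(
                    f"clusters {seen[name]} and {cluster} share nearest "
                    f"prototype {name!r}"
                )
            else:
                seen[name] = cluster
    for note in conflicts:
        logger.warning("prototype labeling: %s", note)
    return PrototypeLabeling(
        names=names, distances=distances, conflicts=conflicts,
        one_to_one=one_to_one,
    )


def participant_similarity(
    z: pd.DataFrame,
    prototypes: pd.DataFrame,
    inverse: str = "negative",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-person profile distance D and inverse similarity to every
    prototype.

    ``prototypes`` is a named table of z-profiles (e.g. labeled cluster
    centers).  ``inverse`` selects the decreasing transform: "negative"
    (-D, the default) or "reciprocal" (1/(1+D)); either preserves the
    similarity ordering.  Persons with missing trait scores are dropped
    (flagged in the log).
    """
    if inverse not in ("negative", "reciprocal"):
        raise ValueError("inverse must be 'negative' or 'reciprocal'")
    frame = z[list(TRAITS)]
    complete = frame.notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "%d persons with missing trait scores excluded from similarity",
            int((~complete).sum()),
        )
    values = frame[complete].to_numpy(dtype=float)
    proto = prototypes[list(TRAITS)].to_numpy(dtype=float)
    d = np.linalg.norm(values[:, None, :] - proto[None, :, :], axis=2)
    d_frame = pd.DataFrame(
        d, index=frame.index[complete], columns=list(prototypes.index)
    )
    sim = -d_frame if inverse == "negative" else 1.0 / (1.0 + d_frame)
    logger.info("inverse similarity transform: %s", inverse)
    return d_frame, sim


def predictive_validity(
    similarity: pd.DataFrame,
    traits: pd.DataFrame,
    criteria: pd.DataFrame,
    alpha: float = 0.001,
) -> dict[str, pd.DataFrame]:
    """Pairwise-complete Pearson correlations of criteria with prototype
    similarities and with raw traits.

    Returns ``{"prototype_r", "prototype_flag", "trait_r", "trait_flag"}``;
    flags mark two-sided p <= alpha (0.001, the conventional panel-study
    reporting threshold).  Zero-variance criteria are reported missing.
    """
    out = {}
    for tag, predictors in (("prototype", similarity),
                            ("trait", traits[list(TRAITS)])):
        overlap = predictors.index.intersection(criteria.index)
        if len(overlap) < 30:
            raise ValueError("need at least 30 overlapping persons")
        r = pd.DataFrame(index=criteria.columns, columns=predictors.columns,
                         dtype=float)
        flag = pd.DataFrame(False, index=criteria.columns,
                            columns=predictors.columns)
        for crit in criteria.columns:
            y_all = criteria.loc[overlap, crit]
            for col in predictors.columns:
                pair = pd.concat(
                    [predictors.loc[overlap, col], y_all], axis=1
                ).dropna()
                if len(pair) < 3 or pair.iloc[:, 1].std() == 0 or \
                        pair.iloc[:, 0].std() == 0:
                    logger.info("correlation undefined for %s x %s", crit, col)
                    continue
                res = pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                r.loc[crit, col] = float(res.statistic)
                flag.loc[crit, col] = bool(res.pvalue <= alpha)
        out[f"{tag}_r"] = r
        out[f"{tag}_flag"] = flag
    return out


def masked_correlation_table(
    r: pd.DataFrame, flag: pd.DataFrame
) -> pd.DataFrame:
    """Blank out cells above the significance threshold (the published
    tables' presentation rule)."""
    return r.where(flag, other=np.nan)


def cluster_profiles(
    z: pd.DataFrame, partition, labeling: PrototypeLabeling | None = None
) -> pd.DataFrame:
    """Per-cluster trait z-means, sizes and membership proportions.

    With a :class:`PrototypeLabeling`, rows are indexed by prototype name.
    """
    labels = np.asarray(partition)
    frame = z[list(TRAITS)]
    if len(labels) != len(frame):
        raise ValueError("partition length must match trait matrix")
    uniq = sorted(set(labels))
    rows = []
    for c in uniq:
        member = labels == c
        if member.sum() == 0:
            raise ValueError(f"cluster {c} is empty")
        profile = frame[member].mean()
        profile["size"] = int(member.sum())
        profile["proportion"] = member.mean()
        rows.append(profile.rename(
            labeling.names[c] if labeling is not None else c
        ))
    table = pd.DataFrame(rows)
    table.index.name = "prototype" if labeling is not None else "cluster"
    return table


def true_prototype_profiles(z: pd.DataFrame, true_labels) -> pd.DataFrame:
    """Observed z-profiles of planted components (ground-truth reference).

    For synthetic data, the profile actually planted for a component is its
    mean observed z-score vector, which differs from the configured means by
    the grand-mean shift and variance normalization of z-scoring.  Clustering
    recovery should be judged against these, not the raw config vectors.
    """
    profiles = cluster_profiles(z, np.asarray(true_labels))
    return profiles[list(TRAITS)]


def write_reference_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="prototype")
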