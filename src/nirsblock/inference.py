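"""Channel-wise t-tests with max-|t| permutation family-wise error control.

For each family (age group x condition-or-contrast x chromophore) the
observed per-channel statistics are compared against the permutation
distribution of the maximum absolute t across the available ROI channels:

* one-sample families flip the sign of each participant's mean signal
  (one Rademacher sign per participant, applied jointly to all of that
  participant's channels, preserving the spatial correlation structure);
* paired families flip the condition labels per participant, which is
  algebraically identical to sign-flipping the within-participant
  differences and shares the same implementation and random stream.

Corrected p-values use the add-one smoothed proportion
``(1 + #{max-|t| >= |t_obs|}) / (1 + n_permutations)``, which is never zero
and is exact for the identity permutation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nirsblock.core import ROI_CHANNELS, ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceParams",
    "PermutationNull",
    "ZeroVarianceError",
    "one_sample_t",
    "paired_t",
    "cohens_d",
    "maxt_null_one_sample",
    "maxt_null_paired",
    "corrected_p",
    "run_family_tests",
    "family_rng",
]


class ZeroVarianceError(ValueError):
    """The test statistic is undefined because the sample variance is zero."""


@dataclass(frozen=True)
class InferenceParams:
    n_permutations: int = 10_000
    alpha: float = 0.05
    roi_channels: tuple[int, ...] = ROI_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class PermutationNull:
    """Max-|t| null distribution for one test family."""

    family: str
    values: np.ndarray  # (n_permutations,) max |t| per permutation
    seed: int
    flips: np.ndarray | None = None  # optional (n_permutations, n_participants) audit

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("max-|t| null values must be >= 0")


# ---------------------------------------------------------------------------
# basic statistics


def _check_values(values: np.ndarray, label: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        raise ValueError(f"{label}: need at least 2 observations, got {len(values)}")
    if values.std(ddof=1) == 0:
        raise ZeroVarianceError(f"{label}: zero variance, t undefined")
    return values


def one_sample_t(values: np.ndarray, label: str = "sample") -> tuple[float, int, float]:
    """One-sample t-test against zero: ``t = mean / (sd / sqrt(n))``.

    Returns ``(t, df, p_uncorrected)`` with a two-tailed p from the t
    distribution, df = n - 1.
    """
    values = _check_values(values, label)
    n = len(values)
    t = values.mean() / (values.std(ddof=1) / np.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def paired_t(
    cond_a: np.ndarray, cond_b: np.ndarray, label: str = "pair"
) -> tuple[float, int, float]:
    """Paired t-test as a one-sample test on within-participant differences
    (a - b).  Inputs must be matched, same length, pairwise non-NaN."""
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"{label}: unmatched participants (lengths {a.shape} vs {b.shape})"
        )
    both = ~(np.isnan(a) | np.isnan(b))
    return one_sample_t(a[both] - b[both], label)


def cohens_d(values: np.ndarray, label: str = "sample") -> float:
    """One-sample / paired-difference effect size ``d = mean / sd``.

    Satisfies ``d = t / sqrt(n)`` for the matching t-test.
    """
    values = _check_values(values, label)
    return float(values.mean() / values.std(ddof=1))


# ---------------------------------------------------------------------------
# permutation nulls


def family_rng(seed: int, family: str) -> tuple[np.random.Generator, int]:
    """One documented random stream per family.

    The family seed is derived from the master seed and a CRC-32 of the
    family label via ``SeedSequence([seed, crc32(family)])`` — stable across
    runs and platforms.
    """
    tag = zlib.crc32(family.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag])), tag


def _maxt_from_signs(
    data: pd.DataFrame, signs: np.ndarray
) -> tuple[np.ndarray, list]:
    """Max over channels of |t| per permutation.

    ``data``: participants x channels, NaN = participant missing on that
    channel.  ``signs``: (n_permutations, n_participants) Rademacher.  A
    channel with fewer than 2 contributors is dropped from the max.
    Exploits that sign flips leave the sum of squares invariant, so only
    the permuted mean needs recomputing.
    """
    m = signs.shape[0]
    maxt = np.zeros(m)
    used = []
    any_channel = False
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        n = int(ok.sum())
        if n < 2:
            logger.warning("channel %s has < 2 contributors; dropped from max", col)
            continue
        xs = x[ok]
        if np.allclose(xs, xs[0]):
            logger.warning("channel %s has zero variance; dropped from max", col)
            continue
        mean_perm = signs[:, ok] @ xs / n
        ss = float(np.sum(xs**2))
        var = (ss - n * mean_perm**2) / (n - 1)
        var = np.clip(var, 1e-300, None)
        t_perm = np.abs(mean_perm) / np.sqrt(var / n)
        maxt = np.maximum(maxt, t_perm)
        used.append(col)
        any_channel = True
    if not any_channel:
        raise ValueError("no channel with >= 2 contributors in this family")
    return maxt, used


def maxt_null_one_sample(
    data: pd.DataFrame,
    params: InferenceParams,
    family: str = "one_sample",
) -> PermutationNull:
    """Sign-flip max-|t| null for a one-sample family.

    ``data`` is a participants x channels table of summary means (NaN for a
    participant missing on a channel).  Per permutation one Rademacher sign
    per participant is applied jointly to all channels; the max of |t| over
    the channels with >= 2 contributors is recorded.
    """
    rng, tag = family_rng(params.seed, family)
    n_participants = data.shape[0]
    signs = rng.integers(0, 2, size=(params.n_permutations, n_participants)) * 2 - 1
    maxt, _ = _maxt_from_signs(data, signs)
    return PermutationNull(family=family, values=maxt, seed=tag, flips=signs)


def maxt_null_paired(
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    params: InferenceParams,
    family: str = "paired",
) -> PermutationNull:
    """Label-swap max-|t| null for a paired family.

    Swapping the condition labels of a participant negates that
    participant's difference, so the null is the sign-flip null on the
    within-participant differences, sharing the one-sample machinery and
    seed stream.
    """
    if not data_a.index.equals(data_b.index) or not data_a.columns.equals(
        data_b.columns
    ):
        missing = sorted(
            set(data_a.index).symmetric_difference(data_b.index)
        )
        raise ValueError(f"unmatched participants between conditions: {missing}")
    return maxt_null_one_sample(data_a - data_b, params, family)


def corrected_p(observed_t: float, null: PermutationNull) -> float:
    """Add-one smoothed permutation p: ``(1 + #{null >= |t|}) / (1 + m)``.

    Ties at the observed magnitude count toward the tail (the identity
    permutation always does); a relative 1e-9 guard absorbs floating-point
    jitter between the vectorized null and the scalar statistic.
    """
    if len(null.values) == 0:
        raise ValueError("empty permutation null")
    thresh = abs(observed_t)
    tol = 1e-9 * max(1.0, thresh)
    b = int(np.sum(null.values >= thresh - tol))
    return (1 + b) / (1 + len(null.values))


# ---------------------------------------------------------------------------
# family orchestration


def _family_table(
    cohort: pd.DataFrame, age_group: str, condition: str, hb_type: str, roi: tuple[int, ...]
) -> pd.DataFrame:
    sub = cohort[
        (cohort["age_group"] == age_group)
        & (cohort["condition"] == condition)
        & (cohort["hb_type"] == hb_type)
        & cohort["included"]
        & cohort["channel"].isin(roi)
    ]
    return sub.pivot_table(
        index="participant", columns="channel", values="mean_change", dropna=False
    )


def run_family_tests(
    cohort: pd.DataFrame,
    params: InferenceParams = InferenceParams(),
    return_nulls: bool = False,
):
    """Run every test family on a tidy cohort table.

    Families are (age group) x (HL vs baseline, LH vs baseline, HL vs LH)
    x (oxy, deoxy).  Each family gets its own max-|t| permutation null over
    the ROI channels and its own seeded random stream.  Returns a results
    DataFrame with columns hb_type, age_group, family, hemisphere, channel,
    n, t, df, d, p_uncorrected, p_corrected (and the nulls, if requested).
    """
    hemi_map = (
        cohort.drop_duplicates("channel").set_index("channel")["hemisphere"].to_dict()
    )
    rows = []
    nulls: dict[str, PermutationNull] = {}
    age_groups = sorted(cohort["age_group"].unique())
    hb_types = [h for h in ("oxy", "deoxy") if h in set(cohort["hb_type"])]
    for age in age_groups:
        for hb_type in hb_types:
            family_specs = [
                ("HL", ("one_sample", "HL")),
                ("LH", ("one_sample", "LH")),
                ("HL_vs_LH", ("paired", None)),
            ]
            for fam_name, (kind, cond) in family_specs:
                label = f"{age}|{fam_name}|{hb_type}"
                if kind == "one_sample":
                    table = _family_table(cohort, age, cond, hb_type, params.roi_channels)
                    if table.empty:
                        logger.warning("family %s empty; skipped", label)
                        continue
                    diff = table
                else:
                    ta = _family_table(cohort, age, "HL", hb_type, params.roi_channels)
                    tb = _family_table(cohort, age, "LH", hb_type, params.roi_channels)
                    if ta.empty or tb.empty:
                        logger.warning("family %s empty; skipped", label)
                        continue
                    tb = tb.reindex(index=ta.index, columns=ta.columns)
                    diff = ta - tb
                try:
                    null = maxt_null_one_sample(diff, params, label)
                except ValueError as exc:
                    logger.warning("family %s skipped: %s", label, exc)
                    continue
                nulls[label] = null
                for ch in diff.columns:
                    x = diff[ch].dropna().to_numpy()
                    if len(x) < 2 or np.allclose(x, x[0] if len(x) else 0):
                        continue
                    t, df, p_unc = one_sample_t(x, label=f"{label} ch{ch}")
                    rows.append(
                        {
                            "hb_type": hb_type,
                            "age_group": age,
                            "family": fam_name,
                            "hemisphere": hemi_map.get(int(ch), ""),
                            "channel": int(ch),
                            "n": len(x),
                            "t": t,
                            "df": df,
                            "d": cohens_d(x),
                            "p_uncorrected": p_unc,
                            "p_corrected": corrected_p(t, null),
                        }
                    )
    results = pd.DataFrame(
        rows,
        columns=[
            "hb_type",
            "age_group",
            "family",
            "hemisphere",
            "channel",
            "n",
            "t",
            "df",
            "d",
            "p_uncorrected",
            "p_corrected",
        ],
    )
    if return_nulls:
        return results, nulls
    return results
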