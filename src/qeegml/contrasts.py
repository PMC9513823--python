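"""Group contrasts: z scores against a baseline class, median z per feature
category, and thresholded broadband-coherence channel-pair maps.

Every subject's feature values are z-scored against the baseline class's
mean and standard deviation; per comparison class the median z per feature
summarizes the group shift in baseline-SD units. The pair map keeps channel
pairs whose broadband (1-40 Hz) coherence median |z| exceeds a threshold,
signed by direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, BandScheme
from .features import feature_category


@dataclass
class ContrastResult:
    """Baseline-referenced z scores and per-class medians."""

    baseline_class: str
    #: per-subject z scores (subjects x features), baseline subjects included
    z: pd.DataFrame
    #: per-class median z per feature (classes x features)
    median_z: pd.DataFrame
    #: features excluded because the baseline SD was zero
    flagged: list[str]
    labels: pd.Series


def zscore_to_baseline(
    table: pd.DataFrame, labels: pd.Series | np.ndarray, baseline_class: str
) -> ContrastResult:
    """Z-score every subject's features against the baseline class.

    Features with zero baseline SD are flagged and omitted from the output.
    """
    labels = pd.Series(np.asarray(labels), index=table.index, name="class")
    base = table[labels == baseline_class]
    if len(base) < 2:
        raise ValueError(f"baseline class {baseline_class!r} needs >= 2 subjects")
    mean = base.mean()
    sd = base.std(ddof=1)
    flagged = sd.index[(sd == 0) | sd.isna()].tolist()
    keep = [c for c in table.columns if c not in flagged]
    z = (table[keep] - mean[keep]) / sd[keep]
    median_z = z.groupby(labels).median()
    return ContrastResult(
        baseline_class=baseline_class, z=z, median_z=median_z,
        flagged=flagged, labels=labels,
    )


def feature_categories(
    columns: pd.Index, bands: BandScheme = DEFAULT_BANDS
) -> pd.Series:
    """Map feature names to contrast categories: relPSD split per band,
    absPSD / Coh / SE / PAC (and bbCoh / demo when present) kept whole."""
    cats = []
    for c in columns:
        cat = feature_category(c)
        if cat == "relPSD":
            cats.append(f"relPSD:{c.rsplit(':', 1)[1]}")
        else:
            cats.append(cat)
    return pd.Series(cats, index=columns, name="category")


def median_z_by_category(
    contrast: ContrastResult, bands: BandScheme = DEFAULT_BANDS
) -> pd.DataFrame:
    """Median of per-feature median z within each category (classes x
    categories)."""
    cats = feature_categories(contrast.median_z.columns, bands)
    out = {}
    for cat in cats.unique():
        cols = cats.index[cats == cat]
        if len(cols) == 0:
            raise ValueError(f"empty category {cat}")
        out[cat] = contrast.median_z[cols].median(axis=1)
    return pd.DataFrame(out)


def coherence_pair_map(
    contrast: ContrastResult,
    comparison_class: str,
    threshold: float = 0.5,
    prefix: str = "bbCoh",
) -> pd.DataFrame:
    """Channel pairs whose broadband-coherence median |z| exceeds the
    threshold, with sign (+1 increase, -1 decrease vs baseline).

    Expects the contrast to have been computed on a table containing
    broadband coherence features named ``bbCoh:<chA>-<chB>``. Returns an
    edge list (chan_a, chan_b, median_z, sign) sorted by |z| descending.
    """
    cols = [c for c in contrast.median_z.columns if c.startswith(prefix + ":")]
    if not cols:
        raise ValueError(f"no {prefix!r} features in contrast table")
    med = contrast.median_z.loc[comparison_class, cols]
    rows = []
    for name, z in med.items():
        if abs(z) > threshold:
            a, b = name.split(":", 1)[1].split("-")
            rows.append({"chan_a": a, "chan_b": b, "median_z": float(z),
                         "sign": int(np.sign(z))})
    df = pd.DataFrame(rows, columns=["chan_a", "chan_b", "median_z", "sign"])
    if len(df):
        df = df.reindex(df["median_z"].abs().sort_values(ascending=False).index)
        df = df.reset_index(drop=True)
    return df


def band_topography(
    contrast: ContrastResult, comparison_class: str, category: str = "relPSD"
) -> pd.DataFrame:
    """Per-channel median z per band for one comparison class (channels x
    bands) — the numeric content of a topographic map."""
    med = contrast.median_z.loc[comparison_class]
    rows: dict[str, dict[str, float]] = {}
    for name, z in med.items():
        parts = name.split(":")
        if parts[0] != category or len(parts) != 3:
            continue
        rows.setdefault(parts[1], {})[parts[2]] = float(z)
    return pd.DataFrame(rows).T
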