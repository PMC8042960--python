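"""Marker selection: depth and average-peak screens plus rank-sum testing.

Candidate loci are first screened on the training cohort: mean spanning
depth strictly above ``depth_min`` (default 30) and mean peak strictly
above ``peak_min`` (default 1.5).  Each survivor is then tested with a
two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of peak values
between MSI-H and MSS samples, and loci with p strictly below ``alpha``
(default 0.01) become the final markers.  Raw p-values are used; an
optional Bonferroni adjustment is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, MarkerTestError, NoMarkersError, SiteParseError

MSI_H = "MSI-H"
MSS = "MSS"
NORMAL = "NORMAL"
LABELS = (MSI_H, MSS, NORMAL)

DEFAULT_DEPTH_MIN = 30.0
DEFAULT_PEAK_MIN = 1.5
DEFAULT_ALPHA = 0.01


@dataclass
class CohortPeaks:
    """Peak and depth matrices (samples x loci) with sample labels."""

    labels: pd.Series          # sample_id -> MSI-H | MSS | NORMAL
    peaks: pd.DataFrame        # samples x site_ids
    depths: pd.DataFrame       # samples x site_ids

    def __post_init__(self):
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise InputError(f"unknown labels {sorted(bad)}; expected {LABELS}")
        if not self.peaks.index.equals(self.depths.index) or not self.peaks.columns.equals(
            self.depths.columns
        ):
            raise InputError("peaks and depths matrices must share samples and sites")
        if not set(self.labels.index) >= set(self.peaks.index):
            raise InputError("every sample in the matrices needs a label")
        if self.peaks.isna().any().any() or self.depths.isna().any().any():
            raise InputError("peak/depth matrices must be dense (fill absent loci with 0)")

    @property
    def training_samples(self) -> pd.Index:
        mask = self.labels.loc[self.peaks.index].isin([MSI_H, MSS])
        return self.peaks.index[mask.to_numpy()]

    def samples_with_label(self, label: str) -> pd.Index:
        mask = self.labels.loc[self.peaks.index] == label
        return self.peaks.index[mask.to_numpy()]


@dataclass(frozen=True)
class MarkerTestResult:
    site_id: str
    avg_depth: float
    avg_peak: float
    p_value: float
    selected: bool


def cohort_from_profiles(
    profiles: dict[str, pd.DataFrame], labels: pd.Series
) -> CohortPeaks:
    """Assemble a cohort from per-sample profile tables (profile_sample)."""
    peaks = pd.DataFrame(
        {sid: df.set_index("site_id")["peak"] for sid, df in profiles.items()}
    ).T.sort_index(axis=1)
    depths = pd.DataFrame(
        {sid: df.set_index("site_id")["spanning_depth"] for sid, df in profiles.items()}
    ).T.sort_index(axis=1)
    return CohortPeaks(labels=labels, peaks=peaks.fillna(0), depths=depths.fillna(0))


def filter_candidates(
    cohort: CohortPeaks,
    depth_min: float = DEFAULT_DEPTH_MIN,
    peak_min: float = DEFAULT_PEAK_MIN,
    depth_over_normals: bool = False,
) -> list[str]:
    """Loci with mean depth > depth_min and mean peak > peak_min (strict).

    Means are taken over the training tumors (MSI-H and MSS); with
    ``depth_over_normals`` the depth screen instead averages over the
    NORMAL samples, mirroring a depth screen on the panel of normals.
    """
    if depth_min < 0 or peak_min < 0:
        raise InputError("thresholds must be >= 0")
    train = cohort.training_samples
    if len(train) == 0:
        raise InputError("cohort has no MSI-H/MSS training samples")
    depth_rows = cohort.samples_with_label(NORMAL) if depth_over_normals else train
    if len(depth_rows) == 0:
        raise InputError("no samples available for the depth screen")
    mean_depth = cohort.depths.loc[depth_rows].mean(axis=0)
    mean_peak = cohort.peaks.loc[train].mean(axis=0)
    keep = (mean_depth > depth_min) & (mean_peak > peak_min)
    return [str(s) for s in cohort.peaks.columns[keep.to_numpy()]]


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Mann-Whitney U p-value, normal approximation.

    Tie-corrected variance with 0.5 continuity correction; symmetric in
    its arguments.  Groups of fewer than two observations are refused.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MarkerTestError("rank-sum test needs >= 2 observations per group")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def select_markers(
    cohort: CohortPeaks,
    depth_min: float = DEFAULT_DEPTH_MIN,
    peak_min: float = DEFAULT_PEAK_MIN,
    alpha: float = DEFAULT_ALPHA,
    depth_over_normals: bool = False,
    bonferroni: bool = False,
) -> list[MarkerTestResult]:
    """Full selection pipeline; returns all candidates, sorted by p-value.

    ``selected`` is True for loci with p strictly below ``alpha``.
    Raises :class:`NoMarkersError` when nothing is selected, because the
    classifier downstream would have no features.
    """
    msih = cohort.samples_with_label(MSI_H)
    mss = cohort.samples_with_label(MSS)
    if len(msih) < 2 or len(mss) < 2:
        raise InputError("marker selection needs >= 2 MSI-H and >= 2 MSS samples")
    candidates = filter_candidates(cohort, depth_min, peak_min, depth_over_normals)
    train = cohort.training_samples
    results = []
    m = len(candidates)
    for site_id in candidates:
        try:
            p = rank_sum_test(
                cohort.peaks.loc[msih, site_id], cohort.peaks.loc[mss, site_id]
            )
        except MarkerTestError as exc:
            warnings.warn(f"site {site_id} dropped: {exc}", stacklevel=2)
            continue
        if bonferroni:
            p = min(1.0, p * m)
        results.append(
            MarkerTestResult(
                site_id=site_id,
                avg_depth=float(cohort.depths.loc[train, site_id].mean()),
                avg_peak=float(cohort.peaks.loc[train, site_id].mean()),
                p_value=p,
                selected=bool(p < alpha),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.site_id))
    if not any(r.selected for r in results):
        raise NoMarkersError(
            f"no marker with p < {alpha} among {len(results)} candidate loci"
        )
    return results


def selected_site_ids(results: list[MarkerTestResult]) -> list[str]:
    return [r.site_id for r in results if r.selected]


def write_markers(results: list[MarkerTestResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tavg_depth\tavg_peak\tp_value\tselected\n")
        for r in results:
            fh.write(
                f"{r.site_id}\t{r.avg_depth!r}\t{r.avg_peak!r}\t{r.p_value!r}\t"
                f"{int(r.selected)}\n"
            )


def read_markers(path: str) -> list[MarkerTestResult]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "site_id\t")):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise SiteParseError(path, i, "expected 5 columns")
            try:
                out.append(
                    MarkerTestResult(
                        site_id=fields[0],
                        avg_depth=float(fields[1]),
                        avg_peak=float(fields[2]),
                        p_value=float(fields[3]),
                        selected=bool(int(fields[4])),
                    )
                )
            except ValueError as exc:
                raise SiteParseError(path, i, str(exc)) from exc
    return out


def read_labels(path: str) -> pd.Series:
    """Read a labels TSV (sample_id, label) into a Series."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "label"} <= set(df.columns):
        raise SiteParseError(path, 1, "labels TSV needs columns sample_id, label")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise SiteParseError(path, 1, f"unknown labels {sorted(bad)}")
    return df.set_index("sample_id")["label"]


def write_labels(labels: pd.Series, path: str) -> None:
    labels.rename("label").rename_axis("sample_id").to_frame().to_csv(path, sep="\t")
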