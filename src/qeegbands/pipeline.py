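"""End-to-end orchestration of the band-power analysis.

``run_analysis`` drives: preprocess -> Welch PSD -> per-channel relative
band power -> zone averages -> omnibus resampling ANOVA per band x zone ->
between-group tests per visit (Kruskal-Wallis plus pairwise rank-sum with
unpaired Cliff's delta) -> within-group between-visit tests (signed-rank
with paired delta, plus a per-electrode paired-delta table) -> pooled
Spearman/FDR correlation matrix with its collapsed view. Everything is
written as tidy CSV plus a JSON run manifest and is deterministic for a
fixed config and seed.

Zone-level deltas are computed on zone-averaged powers (zone averages
first, statistics second), never by averaging per-electrode deltas.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from qeegbands import effect_sizes
from qeegbands.eeg_io import (
    EEGRecording,
    GROUPS,
    Montage,
    default_montage,
    load_montage,
    preprocess,
    read_metadata,
    read_recording,
    read_scores,
)
from qeegbands.spectral import BAND_NAMES, relative_band_power, welch_psd, zone_table
from qeegbands.stats import (
    DEFAULT_ANOVA_ITER,
    DEFAULT_ANOVA_SEED,
    kruskal_wallis,
    resampling_mixed_anova,
    significance_marker,
    spearman_with_fdr,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

__all__ = ["AnalysisConfig", "AnalysisResults", "analyze", "run_analysis", "collapse_correlation_matrix"]

GROUP_PAIRS = (("CRB_rTMS", "CRB_sham"), ("CRB_rTMS", "PLC_sham"), ("CRB_sham", "PLC_sham"))

_CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class AnalysisConfig:
    """Paths and parameters for one analysis run."""

    recordings_dir: str
    metadata_path: str
    scores_path: str
    output_dir: str
    montage_path: str | None = None
    window_s: float = 1.0
    overlap: float = 0.5
    target_fs: float = 512.0
    notch_hz: float = 50.0
    apply_bandpass: bool = False
    anova_iter: int = DEFAULT_ANOVA_ITER
    anova_seed: int = DEFAULT_ANOVA_SEED
    alpha: float = 0.05
    collapse_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class AnalysisResults:
    """All result tables of one run, keyed as written to disk."""

    band_powers: pd.DataFrame
    electrode_powers: pd.DataFrame
    anova: pd.DataFrame
    between_groups: pd.DataFrame
    within_groups: pd.DataFrame
    electrode_paired_delta: pd.DataFrame
    correlations: pd.DataFrame
    collapsed: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "band_powers": self.band_powers,
            "electrode_powers": self.electrode_powers,
            "anova": self.anova,
            "between_groups": self.between_groups,
            "within_groups": self.within_groups,
            "electrode_paired_delta": self.electrode_paired_delta,
            "correlations": self.correlations,
            "collapsed": self.collapsed,
        }


def compute_band_power_tables(
    recordings: Mapping[tuple[str, str], EEGRecording],
    metadata: pd.DataFrame,
    montage: Montage,
    window_s: float = 1.0,
    overlap: float = 0.5,
    target_fs: float = 512.0,
    notch_hz: float | None = 50.0,
    apply_bandpass: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess + PSD + relative band power for every subject-visit.

    Returns (zone-level table, electrode-level table), both tidy.
    """
    zone_rows, electrode_rows = [], []
    for _, meta in metadata.sort_values(["subject_id", "visit"]).iterrows():
        key = (meta.subject_id, meta.visit)
        if key not in recordings:
            raise FileNotFoundError(f"missing recording for subject {meta.subject_id} visit {meta.visit}")
        rec = recordings[key]
        clean = preprocess(rec, target_fs=target_fs, notch_hz=notch_hz, apply_bandpass=apply_bandpass)
        rel = relative_band_power(welch_psd(clean, window_s=window_s, overlap=overlap))
        zones = zone_table(rel, montage)
        for zone, row in zones.iterrows():
            for band in BAND_NAMES:
                zone_rows.append((meta.subject_id, meta.group, meta.visit, zone, band, row[band]))
        for channel, row in rel.iterrows():
            for band in BAND_NAMES:
                electrode_rows.append((meta.subject_id, meta.group, meta.visit, channel, band, row[band]))
    cols = ["subject_id", "group", "visit", "zone", "band", "relative_power"]
    zone_df = pd.DataFrame(zone_rows, columns=cols)
    electrode_df = pd.DataFrame(electrode_rows, columns=[*cols[:3], "channel", "band", "relative_power"])
    return zone_df, electrode_df


def _slice(table: pd.DataFrame, band: str, zone: str) -> pd.DataFrame:
    return table[(table["band"] == band) & (table["zone"] == zone)]


def _visit_values(cell: pd.DataFrame, group: str, visit: str) -> np.ndarray:
    sub = cell[(cell["group"] == group) & (cell["visit"] == visit)]
    return sub.sort_values("subject_id")["relative_power"].to_numpy()


def analyze(
    recordings: Mapping[tuple[str, str], EEGRecording],
    metadata: pd.DataFrame,
    scores: pd.DataFrame,
    montage: Montage | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisResults:
    """Run the full statistical analysis on in-memory inputs."""
    montage = montage or default_montage()
    cfg = config or AnalysisConfig(recordings_dir="", metadata_path="", scores_path="", output_dir="")

    zone_df, electrode_df = compute_band_power_tables(
        recordings, metadata, montage,
        window_s=cfg.window_s, overlap=cfg.overlap,
        target_fs=cfg.target_fs, notch_hz=cfg.notch_hz, apply_bandpass=cfg.apply_bandpass,
    )
    groups_present = [g for g in GROUPS if g in set(metadata["group"])]

    anova_rows, between_rows, within_rows = [], [], []
    for band in BAND_NAMES:
        for zone in montage.zone_names:
            cell = _slice(zone_df, band, zone)

            if len(groups_present) >= 2:
                ar = resampling_mixed_anova(cell, n_iter=cfg.anova_iter, seed=cfg.anova_seed)
                anova_rows.append(
                    (band, zone, ar.p_group, ar.p_visit, ar.p_interaction,
                     significance_marker(ar.p_group), significance_marker(ar.p_visit),
                     significance_marker(ar.p_interaction), ar.n_iter, ar.seed)
                )

            for visit in ("V1", "V2"):
                samples = {g: _visit_values(cell, g, visit) for g in groups_present}
                if len(groups_present) >= 2:
                    kw = kruskal_wallis(list(samples.values()))
                    between_rows.append(
                        (band, zone, visit, "all-groups", kw.method, kw.statistic, kw.p,
                         kw.marker, np.nan, "", sum(kw.n))
                    )
                for gx, gy in GROUP_PAIRS:
                    if gx not in samples or gy not in samples:
                        continue
                    rs = wilcoxon_rank_sum(samples[gx], samples[gy])
                    es = effect_sizes.cliffs_delta(samples[gx], samples[gy])
                    between_rows.append(
                        (band, zone, visit, f"{gx} vs {gy}", rs.method, rs.statistic, rs.p,
                         rs.marker, es.delta, es.label, es.n_x + es.n_y)
                    )

            for group in groups_present:
                v1 = _visit_values(cell, group, "V1")
                v2 = _visit_values(cell, group, "V2")
                sr = wilcoxon_signed_rank(v1, v2)
                es = effect_sizes.paired_cliffs_delta(v1, v2)
                within_rows.append(
                    (band, zone, group, sr.method, sr.statistic, sr.p, sr.marker,
                     es.delta, es.label, es.n_x)
                )

    anova = pd.DataFrame(
        anova_rows,
        columns=["band", "zone", "p_group", "p_visit", "p_interaction",
                 "marker_group", "marker_visit", "marker_interaction", "n_iter", "seed"],
    )
    between = pd.DataFrame(
        between_rows,
        columns=["band", "zone", "visit", "contrast", "method", "statistic", "p", "marker",
                 "delta", "delta_label", "n"],
    )
    within = pd.DataFrame(
        within_rows,
        columns=["band", "zone", "group", "method", "statistic", "p", "marker",
                 "paired_delta", "delta_label", "n"],
    )

    # Figure-6-style per-electrode paired deltas, one row per group x band x channel
    electrode_rows = []
    for group in groups_present:
        for band in BAND_NAMES:
            sub = electrode_df[(electrode_df["group"] == group) & (electrode_df["band"] == band)]
            for channel in montage.labels:
                chan = sub[sub["channel"] == channel]
                v1 = chan[chan["visit"] == "V1"].sort_values("subject_id")["relative_power"].to_numpy()
                v2 = chan[chan["visit"] == "V2"].sort_values("subject_id")["relative_power"].to_numpy()
                if v1.size == 0 or v1.size != v2.size:
                    continue
                es = effect_sizes.paired_cliffs_delta(v1, v2)
                electrode_rows.append((group, band, channel, es.delta, es.label, es.n_x))
    electrode_delta = pd.DataFrame(
        electrode_rows, columns=["group", "band", "channel", "paired_delta", "delta_label", "n"]
    )

    correlations = spearman_with_fdr(scores, zone_df)
    collapsed = collapse_correlation_matrix(correlations, threshold=cfg.collapse_threshold)

    return AnalysisResults(
        band_powers=zone_df, electrode_powers=electrode_df, anova=anova,
        between_groups=between, within_groups=within,
        electrode_paired_delta=electrode_delta,
        correlations=correlations, collapsed=collapsed,
    )


def collapse_correlation_matrix(cells: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Collapse a tidy correlation table to its significant neighbourhood.

    Keeps a (band, zone) row or test column iff it contains at least one
    cell with adjusted p below ``threshold``; returns the rho pivot
    (possibly empty).
    """
    qualifying = cells[cells["p_adj"] < threshold]
    if qualifying.empty:
        return pd.DataFrame()
    keep_rows = set(zip(qualifying["band"], qualifying["zone"]))
    keep_tests = set(qualifying["test"])
    mask = cells.apply(
        lambda r: (r["band"], r["zone"]) in keep_rows and r["test"] in keep_tests, axis=1
    )
    return cells[mask].pivot_table(index=["band", "zone"], columns="test", values="rho")


def _load_recordings(config: AnalysisConfig, metadata: pd.DataFrame) -> dict[tuple[str, str], EEGRecording]:
    rec_dir = Path(config.recordings_dir)
    recordings = {}
    for _, meta in metadata.iterrows():
        stem = f"{meta.subject_id}_{meta.visit}"
        matches = sorted(p for p in rec_dir.glob(f"{stem}.*") if p.suffix != ".vmrk" and p.suffix != ".eeg")
        if not matches:
            raise FileNotFoundError(
                f"no recording named {stem}.* for subject {meta.subject_id} visit {meta.visit} in {rec_dir}"
            )
        rec = read_recording(matches[0])
        rec.subject_id, rec.group, rec.visit = meta.subject_id, meta.group, meta.visit
        recordings[(meta.subject_id, meta.visit)] = rec
    return recordings


def run_analysis(config: AnalysisConfig) -> AnalysisResults:
    """Load inputs per ``config``, analyze, and write CSVs plus a manifest."""
    metadata = read_metadata(config.metadata_path)
    scores = read_scores(config.scores_path)
    montage = load_montage(config.montage_path) if config.montage_path else default_montage()
    recordings = _load_recordings(config, metadata)

    results = analyze(recordings, metadata, scores, montage=montage, config=config)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in results.tables().items():
        path = out_dir / f"{name}.csv"
        if name == "collapsed" and not table.empty:
            table.to_csv(path, float_format=_CSV_FLOAT_FORMAT)
        else:
            table.to_csv(path, index=(name == "collapsed"), float_format=_CSV_FLOAT_FORMAT)
        written[name] = str(path)

    import qeegbands

    manifest = {
        "config": asdict(config),
        "seed": config.anova_seed,
        "package_version": qeegbands.__version__,
        "n_subjects": int(metadata["subject_id"].nunique()),
        "bands": list(BAND_NAMES),
        "zones": list(montage.zone_names),
        "outputs": written,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results.manifest = manifest
    return results
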