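"""End-to-end orchestration: preprocessing, early warnings, FI, RDA.

One flat YAML config drives the whole analysis; all stage outputs are
written as TSV next to a versioned ``summary.json`` aligning the FI
regime segmentation and the RDA axis structure on the common age axis.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ews, fisher, ordination
from .io import CommunityTimeSeries, preprocess, read_community_table, write_series_table

__all__ = ["AnalysisConfig", "SummaryReport", "parse_config", "run_full_analysis"]

log = logging.getLogger("regimeshift")

_DEFAULTS = {
    "input": None,
    "age_column": None,
    "window": 10,
    "sost_scale": 1.0,
    "smoothing_span": 5,
    "slope_tol": 0.5,
    "min_len": 101,
    "alpha": 0.05,
    "n_perm": 999,
    "seed": 0,
    "outdir": "results",
}


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run (defaults in parentheses)."""

    input: str | None = None
    age_column: str | None = None
    window: int = 10              # rolling window, time steps (10)
    sost_scale: float = 1.0       # multiplier on the least-variable-window s.d.
    smoothing_span: int = 5       # mean-FI moving-average span, windows (5)
    slope_tol: float = 0.5        # stable-regime slope tolerance, FI per kyr
    min_len: int = 101            # minimum segment length, windows
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.smoothing_span < 1 or self.smoothing_span % 2 == 0:
            raise ValueError("smoothing_span must be odd and >= 1")


@dataclass
class SummaryReport:
    """Joint summary of the three analyses."""

    schema_version: int
    n_steps: int
    n_species: int
    span: tuple[float, float]                    # (oldest, youngest) age BP
    segments: list[tuple[float, float, str]]
    shift_ages: list[float]
    n_pcnm: int
    n_selected_pcnms: int
    adjusted_r2: float
    n_significant_axes: int
    variance_fraction_raw: list[float]
    variance_fraction_adjusted: list[float]
    axis1_break_age: float | None
    ews_peak_variance_age: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def parse_config(path: str | Path) -> AnalysisConfig:
    """Parse a flat key: value YAML config, applying defaults.

    Unknown keys produce a warning, not an error; malformed YAML raises
    with the offending line number.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ValueError(f"malformed config {path}{line}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key: value mapping")
    known = {}
    for key, value in data.items():
        if key not in _DEFAULTS:
            log.warning("ignoring unknown config key %r", key)
        else:
            known[key] = value
    cfg = AnalysisConfig(**{**_DEFAULTS, **known})
    cfg.validate()
    return cfg


def axis1_break_age(lc1: np.ndarray, ages: np.ndarray) -> float:
    """Age of the largest single-step change in an lc-score track.

    A 3-point median filter is applied first so that one-step spikes
    (flicker excursions) do not mask the sustained level change of a
    regime shift; the age reported is the younger endpoint of the step
    with the largest absolute first difference.
    """
    from scipy.signal import medfilt

    f = medfilt(np.asarray(lc1, dtype=float), 3)
    i = int(np.argmax(np.abs(np.diff(f))))
    return float(ages[i + 1])


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_full_analysis(
    cfg: AnalysisConfig, cts: CommunityTimeSeries | None = None
) -> SummaryReport:
    """Run preprocessing, EWS, FI and RDA with shared options.

    ``cts`` may be passed directly (e.g. a synthetic record); otherwise
    ``cfg.input`` is read.  All stage tables are written under
    ``cfg.outdir`` together with ``summary.json``.  Fixed seed implies
    byte-identical outputs.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("preprocess")
    if cts is None:
        if cfg.input is None:
            raise ValueError("no input table and no in-memory record given")
        cts = read_community_table(cfg.input, age_column=cfg.age_column)
    cts = preprocess(cts)
    log.info("record: %d steps x %d species (%.1fs)",
             cts.n_steps, cts.n_species, time.perf_counter() - t0)

    t0 = _stage("early_warning")
    ews_table = ews.indicators_all_species(cts, window=cfg.window)
    write_series_table(ews_table, outdir / "ews.tsv")
    var_wide = ews_table[ews_table["indicator"] == "variance"]
    peak = {
        sp: float(grp.loc[grp["value"].idxmax(), "age"])
        for sp, grp in var_wide.groupby("species", sort=False)
    }
    log.info("EWS done (%.1fs)", time.perf_counter() - t0)

    t0 = _stage("fisher_information")
    fs = fisher.fi_series(cts, window=cfg.window, sost_scale=cfg.sost_scale)
    fs = fisher.mean_fi(fs, span=cfg.smoothing_span)
    write_series_table(fs, outdir / "fi.tsv")
    seg = fisher.segment_regimes(fs, slope_tol=cfg.slope_tol, min_len=cfg.min_len)
    write_series_table(seg, outdir / "segments.tsv")
    log.info("FI done: %d segments, shifts at %s (%.1fs)",
             len(seg.segments), [round(a) for a in seg.shift_ages],
             time.perf_counter() - t0)

    t0 = _stage("temporal_ordination")
    basis = ordination.build_pcnm(cts.ages)
    Y = ordination.hellinger(cts)
    sel = ordination.forward_select(Y, basis, alpha=cfg.alpha,
                                    n_perm=cfg.n_perm, seed=cfg.seed)
    if sel.selected:
        X = basis.vectors[:, sel.selected]
        model = ordination.fit_rda(Y, X)
        model.selected_pcnms = sel.selected
        model.adjusted_r2 = sel.adj_r2
        ordination.test_axes(model, Y, X, n_perm=cfg.n_perm,
                             alpha=cfg.alpha, seed=cfg.seed + 1)
        lc = ordination.lc_scores(model)
        lc.insert(0, "age", cts.ages)
        write_series_table(lc, outdir / "rda_lc.tsv")
        adj_ratio = (model.adjusted_r2 / model.r2) if model.r2 > 0 else np.nan
        frac_raw = model.variance_fraction
        frac_adj = frac_raw * adj_ratio
        axes_df = lc_axes_table(model, frac_adj)
        write_series_table(axes_df, outdir / "rda_axes.tsv")
        import pandas as pd
        write_series_table(
            pd.DataFrame({"pcnm": [i + 1 for i in sel.selected],
                          "pvalue": sel.pvalues}),
            outdir / "rda_selected.tsv",
        )
        write_series_table(
            pd.DataFrame(model.species_scores, index=cts.species_names,
                         columns=axes_df["axis"]).rename_axis("species").reset_index(),
            outdir / "rda_species.tsv",
        )
        break_age = axis1_break_age(model.lc[:, 0], cts.ages)
        n_sig = int(model.n_significant)
    else:
        model = None
        frac_raw = np.array([])
        frac_adj = np.array([])
        break_age = None
        n_sig = 0
    log.info("RDA done: %d PCNMs, %d selected, %d significant axes (%.1fs)",
             basis.k, len(sel.selected), n_sig, time.perf_counter() - t0)

    report = SummaryReport(
        schema_version=1,
        n_steps=cts.n_steps,
        n_species=cts.n_species,
        span=(float(cts.ages[0]), float(cts.ages[-1])),
        segments=seg.segments,
        shift_ages=seg.shift_ages,
        n_pcnm=basis.k,
        n_selected_pcnms=len(sel.selected),
        adjusted_r2=float(sel.adj_r2),
        n_significant_axes=n_sig,
        variance_fraction_raw=[float(v) for v in frac_raw],
        variance_fraction_adjusted=[float(v) for v in frac_adj],
        axis1_break_age=break_age,
        ews_peak_variance_age=peak,
    )
    report.to_json(outdir / "summary.json")
    return report


def lc_axes_table(model: "ordination.RDAModel", frac_adj: np.ndarray):
    import pandas as pd

    n_axes = len(model.canonical_eigenvalues)
    return pd.DataFrame(
        {
            "axis": [f"RDA{a+1}" for a in range(n_axes)],
            "eigenvalue": model.canonical_eigenvalues,
            "variance_fraction_raw": model.variance_fraction,
            "variance_fraction_adjusted": frac_adj,
            "pvalue": model.axis_pvalues
            if model.axis_pvalues is not None
            else [np.nan] * n_axes,
        }
    )
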