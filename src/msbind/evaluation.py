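"""Cross-validated model evaluation and MS-vs-SS comparison.

The protocol: records are split into k equal folds (k = 10 for the canonical
1,000-spot arrays).  For the MS model a two-pass scheme is used — pass 1 fits
each training set with a free offset alpha, the median of the k fitted alphas
is selected, and pass 2 refits each training set with alpha held at that
median before scoring the test fold.  Prediction error is reported as the
normalized RMSE: RMS error divided by the test fold's sample standard
deviation, so values below 1 beat the trivial mean predictor.

The SS model additionally scans all candidate site offsets r (one per window
position shared by every record) and keeps the offset with the lowest mean
normalized RMSE.  Window-size scans run the matching cross-validation per S
and mark the best S; `compare_models` turns a pair of scans into per-fold
percent decreases of the MS error relative to the SS error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energy_models import MSModel, SSModel, ms_energy, ss_energy
from .fitting import FitConfig, fit_ms, fit_ss
from .spot_io import SpotRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "CVReport",
    "WindowScan",
    "ComparisonReport",
    "make_folds",
    "normalized_rmse",
    "crossval_ms",
    "crossval_ss",
    "scan_windows",
    "compare_models",
    "correlate",
    "ss_candidate_model_count",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A k-fold partition: ``fold_index[i]`` is the fold of record i."""

    k: int
    fold_index: np.ndarray
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_index == fold


def make_folds(n_records: int, k: int, seed: int) -> FoldAssignment:
    """Random equal partition: permute by seed, assign round-robin.

    Fold sizes differ by at most one; n = 1000, k = 10 gives ten folds of
    exactly 100.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_records < k:
        raise ValueError(f"cannot split {n_records} records into {k} folds")
    perm = np.random.default_rng(seed).permutation(n_records)
    fold_index = np.empty(n_records, dtype=np.int64)
    fold_index[perm] = np.arange(n_records) % k
    return FoldAssignment(k=k, fold_index=fold_index, seed=seed)


def normalized_rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """RMS prediction error divided by the sample sd (ddof=1) of ``observed``.

    Values below 1 indicate a prediction better than the mean predictor.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must have equal non-zero length")
    sd = float(np.std(observed, ddof=1)) if observed.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("observed values are constant; normalization undefined")
    rms = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    return rms / sd


def correlate(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CVReport:
    """Per-fold cross-validation outcome for one model kind and window size."""

    kind: Literal["MS", "SS"]
    S: int
    k: int
    seed: int
    n_records: int
    fold_rmse: tuple[float, ...]
    fold_alphas: tuple[float, ...] | None = None  # MS pass-1 alphas
    alpha_selected: float | None = None  # the median, used in pass 2
    site_offset: int | None = None  # SS best site
    per_site_mean_rmse: tuple[tuple[int, float], ...] | None = None
    incomplete: bool = False
    errors: tuple[str, ...] = ()

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.fold_rmse, ddof=1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mean_rmse"] = self.mean_rmse
        d["sd_rmse"] = self.sd_rmse
        return d


def _split(records, folds: FoldAssignment, fold: int):
    test_mask = folds.test_mask(fold)
    train = [rec for rec, m in zip(records, test_mask) if not m]
    test = [rec for rec, m in zip(records, test_mask) if m]
    return train, test


def crossval_ms(
    data: Sequence[SpotRecord],
    S: int,
    k: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
) -> CVReport:
    """Two-pass k-fold cross-validation of the MS model at window size S."""
    config = config or FitConfig()
    records = list(data)
    folds = make_folds(len(records), k, seed)

    alphas: list[float] = []
    errors: list[str] = []
    for f in range(k):
        train, _ = _split(records, folds, f)
        try:
            fit = fit_ms(train, S, config=replace(config, seed=config.seed + f))
            alphas.append(fit.model.alpha)
        except Exception as exc:  # noqa: BLE001 — reported per fold
            errors.append(f"fold {f} pass 1: {exc}")
            alphas.append(np.nan)
    finite = [a for a in alphas if np.isfinite(a)]
    if not finite:
        raise ValueError("all pass-1 fits failed; no alpha to select")
    alpha_med = float(np.median(finite))

    fold_rmse: list[float] = []
    for f in range(k):
        train, test = _split(records, folds, f)
        try:
            fit = fit_ms(
                train,
                S,
                config=replace(config, seed=config.seed + f, fixed_alpha=alpha_med),
            )
            pred = np.array(
                [ms_energy(fit.model, rec.peptide).total for rec in test]
            )
            obs = np.array([rec.pseudo_energy for rec in test])
            fold_rmse.append(normalized_rmse(pred, obs))
        except Exception as exc:  # noqa: BLE001
            errors.append(f"fold {f} pass 2: {exc}")
            fold_rmse.append(np.nan)
    return CVReport(
        kind="MS",
        S=S,
        k=k,
        seed=seed,
        n_records=len(records),
        fold_rmse=tuple(fold_rmse),
        fold_alphas=tuple(alphas),
        alpha_selected=alpha_med,
        incomplete=bool(errors),
        errors=tuple(errors),
    )


def crossval_ss(
    data: Sequence[SpotRecord],
    S: int,
    k: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
) -> CVReport:
    """k-fold CV of the SS model over all candidate sites; returns the best.

    Candidate offsets span the minimum peptide length in the data so every
    record carries the site; the site with the lowest mean normalized RMSE
    wins, ties to the smaller offset.
    """
    config = config or FitConfig()
    records = list(data)
    folds = make_folds(len(records), k, seed)
    n_min = min(rec.peptide.length for rec in records)
    if S > n_min:
        raise ValueError(
            f"window size {S} exceeds minimum peptide length {n_min}"
        )

    best: CVReport | None = None
    site_means: list[tuple[int, float]] = []
    for r in range(n_min - S + 1):
        fold_rmse: list[float] = []
        errors: list[str] = []
        for f in range(k):
            train, test = _split(records, folds, f)
            try:
                fit = fit_ss(train, S, r, config=config)
                pred = np.array(
                    [ss_energy(fit.model, rec.peptide) for rec in test]
                )
                obs = np.array([rec.pseudo_energy for rec in test])
                fold_rmse.append(normalized_rmse(pred, obs))
            except Exception as exc:  # noqa: BLE001
                errors.append(f"site {r} fold {f}: {exc}")
                fold_rmse.append(np.nan)
        report = CVReport(
            kind="SS",
            S=S,
            k=k,
            seed=seed,
            n_records=len(records),
            fold_rmse=tuple(fold_rmse),
            site_offset=r,
            incomplete=bool(errors),
            errors=tuple(errors),
        )
        site_means.append((r, report.mean_rmse))
        if best is None or report.mean_rmse < best.mean_rmse:
            best = report
    assert best is not None
    return replace(best, per_site_mean_rmse=tuple(site_means))


@dataclass(frozen=True)
class WindowScan:
    """Cross-validated RMSE per window size for one model kind."""

    kind: Literal["MS", "SS"]
    reports: tuple[CVReport, ...]  # one per S, ascending
    best_S: int
    k: int
    seed: int
    n_records: int

    @property
    def best(self) -> CVReport:
        for rep in self.reports:
            if rep.S == self.best_S:
                return rep
        raise LookupError(f"no report at S={self.best_S}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.reports:
            for f, rmse in enumerate(rep.fold_rmse):
                rows.append(
                    {
                        "kind": rep.kind,
                        "S": rep.S,
                        "fold": f,
                        "rmse": rmse,
                        "site_offset": rep.site_offset,
                    }
                )
        return pd.DataFrame(rows)


def scan_windows(
    data: Sequence[SpotRecord],
    kind: Literal["MS", "SS"],
    S_values: Sequence[int],
    k: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
) -> WindowScan:
    """Run the matching cross-validation per window size and mark the best S.

    For the MS model the full-length window (S equal to the minimum peptide
    length) is excluded from best-S selection when smaller sizes are in the
    scan: at full length the ensemble has one site and the model degenerates
    to SS.  Ties break toward the smaller S.
    """
    if not S_values:
        raise ValueError("empty window-size range")
    records = list(data)
    n_min = min(rec.peptide.length for rec in records)
    S_sorted = sorted(set(S_values))
    if S_sorted[0] < 1 or S_sorted[-1] > n_min:
        raise ValueError(
            f"window sizes must lie in [1, {n_min}], got {S_sorted}"
        )
    runner = crossval_ms if kind == "MS" else crossval_ss
    reports = tuple(
        runner(records, S, k=k, seed=seed, config=config) for S in S_sorted
    )
    candidates = list(reports)
    if kind == "MS" and len(candidates) > 1:
        candidates = [rep for rep in candidates if rep.S != n_min] or candidates
    best = min(candidates, key=lambda rep: (rep.mean_rmse, rep.S))
    return WindowScan(
        kind=kind,
        reports=reports,
        best_S=best.S,
        k=k,
        seed=seed,
        n_records=len(records),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Per-fold MS-vs-SS percent decrease at each scan's best window size.

    percent_decrease = 100 * (RMSE_SS - RMSE_MS) / RMSE_SS per fold, then
    averaged; positive values mean the MS model predicts better.
    """

    ms_best_S: int
    ss_best_S: int
    ms_fold_rmse: tuple[float, ...]
    ss_fold_rmse: tuple[float, ...]
    fold_percent_decrease: tuple[float, ...]
    mean_percent_decrease: float
    sd_percent_decrease: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_models(ms_scan: WindowScan, ss_scan: WindowScan) -> ComparisonReport:
    """Pair the best-S fold RMSEs of the two scans on identical folds."""
    if ms_scan.kind != "MS" or ss_scan.kind != "SS":
        raise ValueError("expected an MS scan and an SS scan, in that order")
    if (ms_scan.k, ms_scan.seed, ms_scan.n_records) != (
        ss_scan.k,
        ss_scan.seed,
        ss_scan.n_records,
    ):
        raise ValueError("scans were not run on identical folds")
    ms = np.asarray(ms_scan.best.fold_rmse)
    ss = np.asarray(ss_scan.best.fold_rmse)
    pct = 100.0 * (ss - ms) / ss
    return ComparisonReport(
        ms_best_S=ms_scan.best_S,
        ss_best_S=ss_scan.best_S,
        ms_fold_rmse=tuple(ms),
        ss_fold_rmse=tuple(ss),
        fold_percent_decrease=tuple(pct),
        mean_percent_decrease=float(np.mean(pct)),
        sd_percent_decrease=float(np.std(pct, ddof=1)),
    )


def ss_candidate_model_count(n: int) -> int:
    """Number of distinct SS candidate models over all window sizes.

    Summing the N - S + 1 site choices over S = 1..N gives N(N+1)/2; computed
    here by enumeration rather than the closed form.
    """
    return sum(n - S + 1 for S in range(1, n + 1))


def save_report(obj, path) -> None:
    """Serialize a CVReport / WindowScan / ComparisonReport as JSON."""
    if isinstance(obj, (CVReport, ComparisonReport)):
        payload = obj.to_dict()
    elif isinstance(obj, WindowScan):
        payload = {
            "kind": obj.kind,
            "best_S": obj.best_S,
            "k": obj.k,
            "seed": obj.seed,
            "n_records": obj.n_records,
            "reports": [rep.to_dict() for rep in obj.reports],
        }
    else:
        raise TypeError(f"cannot serialize {type(obj)}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=list)
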