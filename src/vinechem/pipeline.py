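"""Config-driven experimental grid: preprocess -> SPXY -> (SPA) -> model -> metrics.

One grid cell is (indicator x preprocessing x wavelength-mode x model). Per
indicator the SPXY split happens once on the raw spectra; preprocessors are
fitted on the training rows only and applied to both sets; SPA selection
sees only the preprocessed training rows; prediction metrics are always
computed on samples never used for fitting or selection. Cell failures are
recorded, never fatal. Reports mirror the usual chemometrics summaries:
metric tables, R2/RPD/RMSE bar charts, predicted-vs-reference scatters of
the winning models, selected-wavelength position plots and CNN loss curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Dataset
from .evaluation import compute_metrics
from .models import ModelSpec, predict, train
from .partitioning import spxy_split
from .preprocessing import Method, PreprocessorSpec, fit, transform
from .selection import SPAConfig, select_wavelengths
from .synthetic import SyntheticConfig, generate_dataset

DEFAULT_PREPROCESSINGS = tuple(
    PreprocessorSpec(method=m)
    for m in (Method.DT, Method.FD, Method.MSC, Method.SG, Method.SNV, Method.SS)
)


@dataclass(frozen=True)
class PipelineConfig:
    dataset: Dataset | None = None
    synthetic: SyntheticConfig | None = None
    indicators: tuple[str, ...] = ("pH", "TSS", "TA", "RS", "TPCN", "TPCD")
    preprocessings: tuple[PreprocessorSpec, ...] = DEFAULT_PREPROCESSINGS
    wavelength_modes: tuple[str, ...] = ("full", "spa")
    models: tuple[ModelSpec, ...] = (
        ModelSpec("pls"), ModelSpec("svr"), ModelSpec("cnn"),
    )
    spa: SPAConfig = field(default_factory=SPAConfig)
    train_fraction: float = 0.7
    #: preprocessing method whose output feeds SPA; None -> run SPA per cell
    spa_preprocessing: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset is None and self.synthetic is None:
            raise ValueError("need a dataset or a synthetic config")
        if not self.indicators or not self.preprocessings or not self.models:
            raise ValueError("sweeps must be non-empty")
        for mode in self.wavelength_modes:
            if mode not in ("full", "spa"):
                raise ValueError(f"unknown wavelength mode {mode!r}")


@dataclass
class GridResult:
    records: list[dict]

    def to_json(self) -> str:
        return json.dumps(self.records, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GridResult":
        return cls(records=json.loads(text))


@dataclass
class BestModelReport:
    winners: dict[str, dict | None]      # indicator -> winning record
    runner_ups: dict[str, list[dict]]

    def to_json(self) -> str:
        return json.dumps(
            {"winners": self.winners, "runner_ups": self.runner_ups},
            indent=1, sort_keys=True,
        )


def _resolve_dataset(config: PipelineConfig) -> Dataset:
    if config.dataset is not None:
        return config.dataset
    return generate_dataset(config.synthetic).as_dataset()


def run_grid(config: PipelineConfig) -> GridResult:
    """Execute the full experimental grid; one record per cell."""
    ds = _resolve_dataset(config)
    X = ds.spectra.reflectance
    wavelengths = ds.spectra.grid.values
    records: list[dict] = []

    for indicator in config.indicators:
        y = ds.references.indicator(indicator)
        split = spxy_split(X, y, config.train_fraction, indicator)
        tr, te = list(split.train_indices), list(split.test_indices)
        ytr, yte = y[tr], y[te]

        for prep in config.preprocessings:
            try:
                fp = fit(prep, X[tr], wavelengths)
                Xtr = transform(fp, X[tr])
                Xte = transform(fp, X[te]) if te else np.empty((0, X.shape[1]))
            except Exception as exc:  # record, keep sweeping
                for mode in config.wavelength_modes:
                    for mspec in config.models:
                        records.append(_failure(indicator, prep, mode, mspec, exc))
                continue

            selection = None
            if "spa" in config.wavelength_modes and (
                config.spa_preprocessing is None
                or prep.method.value == config.spa_preprocessing
            ):
                try:
                    selection = select_wavelengths(Xtr, ytr, config.spa)
                except Exception as exc:
                    selection = exc

            for mode in config.wavelength_modes:
                if mode == "spa":
                    if isinstance(selection, Exception) or selection is None:
                        for mspec in config.models:
                            records.append(_failure(
                                indicator, prep, mode, mspec,
                                selection or RuntimeError("no SPA selection"),
                            ))
                        continue
                    cols = list(selection.selected_indices)
                else:
                    cols = list(range(X.shape[1]))

                for mspec in config.models:
                    records.append(_run_cell(
                        indicator, prep, mode, mspec,
                        Xtr[:, cols], ytr, Xte[:, cols], yte,
                        wavelengths, cols,
                        selection if mode == "spa" else None,
                    ))
    return GridResult(records=records)


def _cell_key(indicator, prep: PreprocessorSpec, mode, mspec: ModelSpec) -> dict:
    return {
        "indicator": indicator,
        "preprocessing": prep.method.value,
        "wavelength_mode": mode,
        "model": mspec.algorithm,
    }


def _failure(indicator, prep, mode, mspec, exc) -> dict:
    rec = _cell_key(indicator, prep, mode, mspec)
    rec.update({"error": f"{type(exc).__name__}: {exc}"})
    return rec


def _run_cell(
    indicator, prep, mode, mspec, Xtr, ytr, Xte, yte,
    wavelengths, cols, selection,
) -> dict:
    rec = _cell_key(indicator, prep, mode, mspec)
    try:
        model = train(mspec, Xtr, ytr, X_eval=Xte if len(yte) else None,
                      y_eval=yte if len(yte) else None)
        cal = compute_metrics(ytr, predict(model, Xtr))
        pred = compute_metrics(yte, predict(model, Xte)) if len(yte) >= 2 else None
        rec.update({
            "error": None,
            "calibration": _finite(cal.as_dict()),
            "prediction": _finite(pred.as_dict()) if pred else None,
            "hyper": _jsonable(model.diagnostics),
            "y_test": list(map(float, yte)),
            "y_test_pred": list(map(float, predict(model, Xte))) if len(yte) else [],
        })
        if mode == "spa" and selection is not None:
            rec["selected_wavelengths_nm"] = [
                float(wavelengths[i]) for i in selection.selected_indices
            ]
            rec["selected_indices"] = list(map(int, selection.selected_indices))
        if model.history is not None:
            rec["loss_train"] = model.history.train_loss
            rec["loss_eval"] = model.history.eval_loss
    except Exception as exc:
        rec["error"] = f"{type(exc).__name__}: {exc}"
    return rec


def _finite(d: dict) -> dict:
    return {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
            for k, v in d.items()}


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            continue  # large arrays (PLS coefficients) stay in memory only
        if isinstance(v, (np.integer, np.floating)):
            v = v.item()
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# Best-model selection


def _rank_key(rec: dict) -> tuple:
    simplicity = {"pls": 0, "svr": 1, "cnn": 2}
    pred = rec.get("prediction") or {}
    r2 = pred.get("r2")
    rpd = pred.get("rpd")
    rmse = pred.get("rmse")
    return (
        -(r2 if r2 is not None else -np.inf),
        -(rpd if rpd is not None else np.inf if rmse == 0 else -np.inf),
        rmse if rmse is not None else np.inf,
        simplicity.get(rec.get("model"), 99),
    )


def select_best(grid: GridResult) -> BestModelReport:
    """Winner per indicator: max prediction R2, ties by RPD, RMSE, simplicity."""
    winners: dict[str, dict | None] = {}
    runner_ups: dict[str, list[dict]] = {}
    indicators = sorted({r["indicator"] for r in grid.records})
    for indicator in indicators:
        ok = [r for r in grid.records
              if r["indicator"] == indicator
              and r.get("error") is None and r.get("prediction")]
        if not ok:
            winners[indicator] = None
            runner_ups[indicator] = []
            continue
        ranked = sorted(ok, key=_rank_key)
        winners[indicator] = ranked[0]
        runner_ups[indicator] = [
            _cell_key_from(r) | {"prediction": r["prediction"]}
            for r in ranked[1:4]
        ]
    return BestModelReport(winners=winners, runner_ups=runner_ups)


def _cell_key_from(rec: dict) -> dict:
    return {k: rec[k] for k in
            ("indicator", "preprocessing", "wavelength_mode", "model")}


# ---------------------------------------------------------------------------
# Reports


def render_reports(grid: GridResult, best: BestModelReport,
                   outdir: str | Path) -> list[Path]:
    """Write CSV summaries and diagnostic plots; returns the files written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    (outdir / "plots").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for r in grid.records:
        row = _cell_key_from(r) | {"error": r.get("error")}
        for which in ("calibration", "prediction"):
            m = r.get(which) or {}
            for k in ("r2", "rmse", "rpd", "n"):
                row[f"{which}_{k}"] = m.get(k)
        rows.append(row)
    summary = outdir / "summary.csv"
    pd.DataFrame(rows).to_csv(summary, index=False)
    written.append(summary)

    best_path = outdir / "best_models.json"
    best_path.write_text(best.to_json())
    written.append(best_path)

    df = pd.DataFrame(rows)
    for indicator, sub in df.groupby("indicator"):
        sub = sub.dropna(subset=["prediction_r2"])
        if sub.empty:
            continue
        labels = (sub["preprocessing"] + "-" + sub["model"] + "-"
                  + sub["wavelength_mode"])
        fig, axes = plt.subplots(2, 1, figsize=(10, 7), sharex=True)
        axes[0].bar(labels, sub["prediction_r2"], color="#4c72b0")
        axes[0].set_ylabel("prediction R$^2$")
        axes[1].bar(labels, sub["prediction_rmse"], color="#c44e52")
        axes[1].set_ylabel("RMSEP")
        axes[1].tick_params(axis="x", rotation=90)
        fig.suptitle(indicator)
        fig.tight_layout()
        path = outdir / "plots" / f"metrics_{indicator}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    for indicator, rec in best.winners.items():
        if not rec:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(rec["y_test"], rec["y_test_pred"], s=18)
        lims = [min(rec["y_test"]), max(rec["y_test"])]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"reference {indicator}")
        ax.set_ylabel(f"predicted {indicator}")
        ax.set_title(
            f"{rec['preprocessing']}-{rec['model']}-{rec['wavelength_mode']}"
        )
        fig.tight_layout()
        path = outdir / "plots" / f"scatter_{indicator}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    for r in grid.records:
        if r.get("selected_wavelengths_nm") and r.get("error") is None:
            fig, ax = plt.subplots(figsize=(8, 2.2))
            ax.vlines(r["selected_wavelengths_nm"], 0, 1, color="#55a868")
            ax.set_xlabel("wavelength (nm)")
            ax.set_yticks([])
            ax.set_title(f"SPA picks: {r['indicator']} ({r['preprocessing']})")
            fig.tight_layout()
            path = (outdir / "plots" /
                    f"spa_{r['indicator']}_{r['preprocessing']}.png")
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
            break  # one representative position plot per render

    for r in grid.records:
        if r.get("loss_train") and r.get("error") is None:
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(r["loss_train"], label="calibration")
            if r.get("loss_eval"):
                ax.plot(r["loss_eval"], label="prediction")
            ax.set_xlabel("epoch")
            ax.set_ylabel("MSE loss")
            ax.set_title(f"CNN loss: {r['indicator']} ({r['preprocessing']})")
            ax.legend()
            fig.tight_layout()
            path = (outdir / "plots" /
                    f"cnn_loss_{r['indicator']}_{r['preprocessing']}.png")
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
            break
    return written
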