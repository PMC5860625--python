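"""Readers and writers for spectra, histograms, models and calibrations.

Formats are deliberately plain: profile spectra arrive as mzML (via
pyteomics) or two-column CSV/TSV; peak histograms travel as one CSV matrix
(rows = spectra, columns = peak centroids) with a sidecar metadata CSV;
models and calibrations are JSON documents.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lpm import ComponentPMF, LPMModel, SpectrumFit
from .preprocess import PeakBinSet, PeakHistogram, RawSpectrum
from .quantify import ClassCalibration, MixtureTruth, Prediction

__all__ = [
    "read_spectrum_table",
    "read_mzml",
    "read_manifest",
    "write_binset",
    "read_binset",
    "write_histograms",
    "read_histograms",
    "write_truth",
    "read_truth",
    "model_to_dict",
    "model_from_dict",
    "write_model",
    "read_model",
    "calibration_to_dict",
    "calibration_from_dict",
    "write_calibration",
    "read_calibration",
    "write_fits",
    "write_predictions",
]


# -- raw spectra -----------------------------------------------------------

def read_spectrum_table(
    path: str | Path, sample_id: str = "", replicate: int = 0
) -> RawSpectrum:
    """Read a two-column (m/z, intensity) CSV or TSV profile spectrum."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    # tolerate a header row
    try:
        mz = df.iloc[:, 0].astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:]
        mz = df.iloc[:, 0].astype(float)
    intensity = df.iloc[:, 1].astype(float)
    sid = sample_id or path.stem
    return RawSpectrum(mz.to_numpy(), intensity.to_numpy(), sid, replicate)


def read_mzml(path: str | Path) -> list[RawSpectrum]:
    """Read all profile spectra from an mzML file."""
    from pyteomics import mzml  # deferred: only needed for mzML input

    spectra = []
    with mzml.read(str(path)) as reader:
        for i, scan in enumerate(reader):
            spectra.append(
                RawSpectrum(
                    np.asarray(scan["m/z array"], dtype=float),
                    np.asarray(scan["intensity array"], dtype=float),
                    sample_id=scan.get("id", f"scan{i}"),
                    replicate=i,
                )
            )
    return spectra


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV: file, sample_id, replicate and optionally fraction_A."""
    df = pd.read_csv(path)
    required = {"file", "sample_id"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must provide columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


# -- peak bins -------------------------------------------------------------

def write_binset(bins: PeakBinSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# window,{bins.window[0]},{bins.window[1]}\n")
        pd.DataFrame(
            {"low": bins.low, "high": bins.high, "centroid": bins.centroid}
        ).to_csv(fh, index=False)


def read_binset(path: str | Path) -> PeakBinSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# window"):
            raise ValueError(f"{path}: missing '# window' header line")
        _, lo, hi = header.split(",")
        df = pd.read_csv(fh)
    return PeakBinSet(
        df["low"].to_numpy(), df["high"].to_numpy(), df["centroid"].to_numpy(),
        window=(float(lo), float(hi)),
    )


# -- histograms ------------------------------------------------------------

def write_histograms(
    histograms: Sequence[PeakHistogram],
    matrix_path: str | Path,
    meta_path: str | Path,
    truth: Sequence[MixtureTruth] | None = None,
) -> None:
    """Histogram corpus as a counts matrix CSV plus a metadata sidecar CSV."""
    centroids = histograms[0].centroids
    matrix = pd.DataFrame(
        np.stack([h.counts for h in histograms]),
        index=[h.sample_id for h in histograms],
        columns=[f"{c:.4f}" for c in centroids],
    )
    matrix.index.name = "sample_id"
    matrix.to_csv(matrix_path)

    meta = pd.DataFrame(
        {
            "sample_id": [h.sample_id for h in histograms],
            "replicate": [h.replicate for h in histograms],
            "gain": [h.gain for h in histograms],
        }
    )
    if truth is not None:
        frac = {t.sample_id: t.fraction_A for t in truth}
        meta["fraction_A"] = [frac.get(s, np.nan) for s in meta["sample_id"]]
    meta.to_csv(meta_path, index=False)


def read_histograms(
    matrix_path: str | Path, meta_path: str | Path
) -> tuple[list[PeakHistogram], list[MixtureTruth] | None]:
    matrix = pd.read_csv(matrix_path, index_col="sample_id")
    meta = pd.read_csv(meta_path).set_index("sample_id")
    centroids = np.array([float(c) for c in matrix.columns])
    histograms = []
    for sid, row in matrix.iterrows():
        m = meta.loc[sid]
        histograms.append(
            PeakHistogram(
                centroids,
                row.to_numpy(dtype=float),
                gain=float(m["gain"]),
                sample_id=str(sid),
                replicate=int(m["replicate"]),
            )
        )
    truth = None
    if "fraction_A" in meta.columns and meta["fraction_A"].notna().all():
        truth = [
            MixtureTruth(str(sid), float(meta.loc[sid, "fraction_A"]))
            for sid in matrix.index
        ]
    return histograms, truth


def write_truth(truth: Sequence[MixtureTruth], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": [t.sample_id for t in truth],
         "fraction_A": [t.fraction_A for t in truth]}
    ).to_csv(path, index=False)


def read_truth(path: str | Path) -> list[MixtureTruth]:
    df = pd.read_csv(path)
    return [
        MixtureTruth(str(r.sample_id), float(r.fraction_A)) for r in df.itertuples()
    ]


# -- models ----------------------------------------------------------------

def model_to_dict(model: LPMModel) -> dict:
    meta = {
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in model.training_meta.items()
        if k != "loglik_trace"  # in-memory diagnostic, not part of the document
    }
    return {
        "centroids": model.centroids.tolist(),
        "components": [c.probs.tolist() for c in model.components],
        "labels": [c.label for c in model.components],
        "K": model.K,
        "chi2_per_dof": model.chi2_per_dof,
        "training_meta": meta,
    }


def model_from_dict(doc: dict) -> LPMModel:
    comps = [
        ComponentPMF(np.asarray(p), label=lab)
        for p, lab in zip(doc["components"], doc.get("labels", [""] * doc["K"]))
    ]
    return LPMModel(
        components=comps,
        centroids=np.asarray(doc["centroids"]),
        K=int(doc["K"]),
        chi2_per_dof=float(doc["chi2_per_dof"]),
        training_meta=dict(doc.get("training_meta", {})),
    )


def write_model(model: LPMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path: str | Path) -> LPMModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# -- calibrations ----------------------------------------------------------

def calibration_to_dict(cal: ClassCalibration) -> dict:
    return {
        "assignment": cal.assignment,
        "efficiency": [None if np.isnan(e) else float(e) for e in cal.efficiency],
        "slope": cal.slope,
        "intercept": cal.intercept,
        "precision": cal.precision,
        "correlations": None
        if cal.correlations is None
        else [float(c) for c in cal.correlations],
    }


def calibration_from_dict(doc: dict) -> ClassCalibration:
    eff = np.array([np.nan if e is None else e for e in doc["efficiency"]], dtype=float)
    corr = doc.get("correlations")
    return ClassCalibration(
        assignment=list(doc["assignment"]),
        efficiency=eff,
        slope=float(doc["slope"]),
        intercept=float(doc["intercept"]),
        precision=float(doc["precision"]),
        correlations=None if corr is None else np.asarray(corr, dtype=float),
    )


def write_calibration(cal: ClassCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(calibration_to_dict(cal), indent=1))


def read_calibration(path: str | Path) -> ClassCalibration:
    return calibration_from_dict(json.loads(Path(path).read_text()))


# -- fits and predictions --------------------------------------------------

def write_fits(
    fits: Sequence[SpectrumFit],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Fits CSV: sample_id, Q_1..Q_K, sigma_1..sigma_K, chi2_per_dof."""
    K = fits[0].weights.size
    rows = []
    for sid, f in zip(sample_ids, fits):
        row = {"sample_id": sid}
        row.update({f"Q_{k + 1}": f.weights[k] for k in range(K)})
        row.update({f"sigma_{k + 1}": f.errors[k] for k in range(K)})
        row["chi2_per_dof"] = f.chi2_per_dof
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_predictions(
    predictions: Sequence[Prediction],
    sample_ids: Sequence[str],
    path: str | Path,
    truth: Sequence[MixtureTruth] | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "proportion": [p.proportion for p in predictions],
            "predicted_error": [p.error for p in predictions],
            "unclipped": [p.unclipped for p in predictions],
        }
    )
    if truth is not None:
        frac = {t.sample_id: t.fraction_A for t in truth}
        df["truth"] = [frac.get(s, np.nan) for s in df["sample_id"]]
    df.to_csv(path, index=False)
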