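"""Session container I/O, unit QC, configuration, and the pipeline driver.

Sessions are stored in a single HDF5 file with groups ``/angle``,
``/spikes``, ``/pupil``, ``/truth``, ``/params``; analysis results are
written as delimited-text tables that embed the configuration snapshot and
its content hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import kinematics, phase_coding, spectral, state_activity, xcorr
from .containers import (AngleTrace, PupilTrace, SessionContainer, SpikeTrain,
                         WHISKING)
from .synth import SessionParams, SyntheticSession

log = logging.getLogger("whisklab")

__all__ = [
    "AnalysisConfig", "classify_waveform", "epoch_split", "run_pipeline",
    "save_session", "load_session", "session_from_synthetic",
    "write_results", "export_session_text", "read_angle_text",
    "save_eye_frames",
]


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, serialized with the results."""

    bandpass_lo: float = 4.0                 # Hz
    bandpass_hi: float = 30.0                # Hz
    threshold_frac: float = 0.2              # fraction of max amplitude
    threshold_mode: str = "max"              # 'max' or 'p99'
    min_bout_dur: float = 0.25               # s
    bin_width: float = 0.010                 # s, cross-correlation bins
    max_lag: float = 2.0                     # s
    n_phase_bins: int = 32
    peak_trough_depth: bool = False
    bonferroni_n: Optional[int] = None       # default: number of units
    taper_nw: float = 3.0
    taper_k: int = 5
    spectral_window: float = 10.0            # s
    spectral_overlap: float = 0.5
    band_low: tuple = (0.5, 5.0)             # Hz
    band_high: tuple = (8.0, 13.0)           # Hz
    n_shuffles: int = 50
    shuffle_margin: float = 10.0             # s
    exclude_narrow: bool = True
    narrow_half_width: float = 0.25e-3       # s
    pupil_radius_range: tuple = (10, 40)     # px
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.bandpass_lo < self.bandpass_hi:
            raise ValueError("bad bandpass edges")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.bin_width <= 0 or self.max_lag <= 0:
            raise ValueError("bin width and max lag must be positive")
        if self.n_phase_bins < 4:
            raise ValueError("need at least 4 phase bins")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        d = yaml.safe_load(text) or {}
        for key in ("band_low", "band_high", "pupil_radius_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def classify_waveform(waveform: np.ndarray, sampling_rate: float,
                      baseline: float = 0.0,
                      narrow_half_width: float = 0.25e-3) -> str:
    """Classify a mean waveform as 'broad' or 'narrow' spiking.

    Half-width is the time from the point of maximum negativity back to
    baseline; units with half-width strictly below 0.25 ms are
    narrow-spiking (putative inhibitory) and excluded from analysis by
    default.  A half-width of exactly 0.25 ms is broad.
    """
    w = np.asarray(waveform, dtype=float)
    trough = int(np.argmin(w))
    if w[trough] >= baseline:
        raise ValueError("waveform has no trough below baseline")
    after = w[trough:]
    above = np.flatnonzero(after >= baseline)
    if above.size == 0:
        raise ValueError("waveform never returns to baseline")
    j = int(above[0])
    # sub-sample crossing by linear interpolation
    if j > 0:
        frac = (baseline - after[j - 1]) / (after[j] - after[j - 1])
        cross = j - 1 + frac
    else:
        cross = 0.0
    half_width = cross / sampling_rate
    return "narrow" if half_width < narrow_half_width else "broad"


def _cut_trace(samples: np.ndarray, frame_rate: float, t0: float,
               t1: float) -> np.ndarray:
    i0 = int(round(t0 * frame_rate))
    i1 = int(round(t1 * frame_rate))
    return samples[i0:i1]


def epoch_split(session: SessionContainer, label: str) -> list:
    """Cut a session into the epochs carrying the given condition label.

    Each returned sub-session is rebased to t = 0 at its epoch start;
    kinematics are meant to be recomputed per (concatenated) condition.
    """
    epochs = session.epochs_for(label)
    if not epochs:
        raise ValueError(f"no epochs labelled {label!r}")
    fs = session.angle.frame_rate
    out = []
    for t0, t1 in epochs:
        ang = AngleTrace(_cut_trace(session.angle.samples, fs, t0, t1), fs)
        units = []
        for u in session.units:
            keep = (u.times >= t0) & (u.times < t1)
            units.append(SpikeTrain(u.times[keep] - t0, unit_id=u.unit_id,
                                    waveform=u.waveform,
                                    waveform_fs=u.waveform_fs))
        pup = None
        if session.pupil is not None:
            pup = PupilTrace(_cut_trace(session.pupil.diameter,
                                        session.pupil.frame_rate, t0, t1),
                             session.pupil.frame_rate)
        out.append(SessionContainer(angle=ang, units=units, pupil=pup,
                                    metadata={**session.metadata,
                                              "epoch": (label, t0, t1)}))
    return out


# ---------------------------------------------------------------------------
# HDF5 container


def save_session(path, session) -> None:
    """Write a :class:`SessionContainer` or :class:`SyntheticSession`."""
    with h5py.File(path, "w") as f:
        if isinstance(session, SyntheticSession):
            container = session_from_synthetic(session)
            truth = f.create_group("truth")
            truth.create_dataset("envelope", data=session.true_envelope)
            truth.create_dataset("phase", data=session.true_phase)
            truth.create_dataset("state", data=session.true_state)
            pg = f.create_group("params")
            pg.attrs["json"] = json.dumps(dataclasses.asdict(session.params))
        else:
            container = session
        ag = f.create_group("angle")
        ag.create_dataset("samples", data=container.angle.samples)
        ag.attrs["frame_rate"] = container.angle.frame_rate
        ag.attrs["t0"] = container.angle.t0
        sg = f.create_group("spikes")
        for u in container.units:
            ds = sg.create_dataset(f"unit_{u.unit_id:04d}", data=u.times)
            if u.waveform is not None:
                ds.attrs["waveform"] = u.waveform
                ds.attrs["waveform_fs"] = u.waveform_fs
        if container.pupil is not None:
            pg = f.create_group("pupil")
            pg.create_dataset("diameter", data=container.pupil.diameter)
            pg.create_dataset("valid", data=container.pupil.valid)
            pg.attrs["frame_rate"] = container.pupil.frame_rate
        if container.condition_epochs:
            eg = f.create_group("epochs")
            eg.attrs["json"] = json.dumps(container.condition_epochs)
        f.attrs["metadata"] = json.dumps(container.metadata, default=str)


def load_session(path) -> SessionContainer:
    with h5py.File(path, "r") as f:
        ag = f["angle"]
        angle = AngleTrace(ag["samples"][()], float(ag.attrs["frame_rate"]),
                           float(ag.attrs.get("t0", 0.0)))
        units = []
        if "spikes" in f:
            for name in sorted(f["spikes"]):
                ds = f["spikes"][name]
                wf = ds.attrs.get("waveform")
                units.append(SpikeTrain(
                    ds[()], unit_id=int(name.split("_")[1]),
                    waveform=None if wf is None else np.asarray(wf),
                    waveform_fs=ds.attrs.get("waveform_fs")))
        pupil = None
        if "pupil" in f:
            pg = f["pupil"]
            pupil = PupilTrace(pg["diameter"][()],
                               float(pg.attrs["frame_rate"]),
                               valid=pg["valid"][()])
        epochs = []
        if "epochs" in f:
            epochs = [tuple(e) for e in json.loads(f["epochs"].attrs["json"])]
        metadata = json.loads(f.attrs.get("metadata", "{}"))
    return SessionContainer(angle=angle, units=units, pupil=pupil,
                            condition_epochs=epochs, metadata=metadata)


def load_truth(path) -> dict:
    """Ground truth and generator parameters of a stored synthetic session."""
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise KeyError("session file carries no ground truth")
        out = {k: f["truth"][k][()] for k in f["truth"]}
        if "params" in f:
            d = json.loads(f["params"].attrs["json"])
            d["carrier_band"] = tuple(d["carrier_band"])
            out["params"] = SessionParams(**d)
    return out


def session_from_synthetic(s: SyntheticSession) -> SessionContainer:
    return SessionContainer(angle=s.angle, units=[s.spikes], pupil=s.pupil,
                            metadata={"synthetic": True,
                                      "seed": s.params.seed})


def export_session_text(session: SessionContainer, outdir) -> None:
    """Delimited-text mirror: one column per trace, spike times per line."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"frame": np.arange(session.angle.n_frames),
                  "angle_deg": session.angle.samples}
                 ).to_csv(outdir / "angle.csv", index=False)
    if session.pupil is not None:
        pd.DataFrame({"frame": np.arange(session.pupil.diameter.size),
                      "diameter": session.pupil.diameter,
                      "valid": session.pupil.valid}
                     ).to_csv(outdir / "pupil.csv", index=False)
    for u in session.units:
        np.savetxt(outdir / f"spikes_unit_{u.unit_id:04d}.txt", u.times,
                   fmt="%.6f")


def read_angle_text(path, frame_rate: float) -> AngleTrace:
    """Angle trace from delimited text with (frame, angle) columns."""
    tab = pd.read_csv(path)
    col = "angle_deg" if "angle_deg" in tab else tab.columns[-1]
    return AngleTrace(tab[col].to_numpy(dtype=float), frame_rate)


def save_eye_frames(path, frames: np.ndarray) -> None:
    """Eye-image stack as one multi-frame TIFF (grey levels in [0, 1])."""
    import tifffile
    stack = np.clip(np.asarray(frames, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, (stack * 65535).astype(np.uint16))


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(session: SessionContainer,
                 config: Optional[AnalysisConfig] = None) -> dict:
    """Run kinematics → rates → phase → cross-correlation → coherence.

    Returns a bundle of per-cell tables (pandas DataFrames) plus the
    kinematic decomposition and the configuration snapshot.
    """
    config = AnalysisConfig() if config is None else config
    config.validate()
    fs = session.angle.frame_rate
    log.info("kinematics: %d frames at %.1f Hz", session.angle.n_frames, fs)
    dec = kinematics.decompose(
        session.angle, lowcut=config.bandpass_lo, highcut=config.bandpass_hi,
        threshold_frac=config.threshold_frac, min_dur=config.min_bout_dur,
        threshold_mode=config.threshold_mode)

    units = list(session.units)
    qc = []
    for u in units:
        label = "unclassified"
        if u.waveform is not None and u.waveform_fs:
            label = classify_waveform(u.waveform, u.waveform_fs,
                                      narrow_half_width=config.narrow_half_width)
        qc.append((u.unit_id, label))
    qc_table = pd.DataFrame(qc, columns=["unit_id", "waveform_class"])
    if config.exclude_narrow:
        excluded = {uid for uid, lab in qc if lab == "narrow"}
        units = [u for u in units if u.unit_id not in excluded]

    n_cells = max(len(units), 1)
    bonf_n = config.bonferroni_n or n_cells
    duration = session.angle.duration

    rate_rows, phase_rows, xc_rows = [], [], []
    coh_rows = []
    amp_z = xcorr.bin_and_zscore(dec.amplitude, config.bin_width,
                                 frame_rate=fs)
    for u in units:
        log.info("unit %d: %d spikes", u.unit_id, u.n_spikes)
        r = state_activity.state_firing_rates(u, dec.state, fs)
        rate_rows.append({
            "unit_id": u.unit_id, "rate_quiescent": r.rate_quiescent,
            "rate_whisking": r.rate_whisking,
            "percent_change": state_activity.percent_change(
                r.rate_quiescent, r.rate_whisking),
            "time_quiescent": r.time_quiescent,
            "time_whisking": r.time_whisking})
        try:
            tun = phase_coding.phase_tuning(
                u, dec.phase, dec.state, fs, n_bins=config.n_phase_bins,
                peak_trough_depth=config.peak_trough_depth,
                bonferroni_n=bonf_n)
            phase_rows.append({
                "unit_id": u.unit_id, "depth": tun.modulation_depth,
                "preferred_phase": tun.preferred_phase,
                "kuiper_v": tun.kuiper_v, "p_raw": tun.p_raw,
                "p_bonferroni": tun.p_corrected,
                "significant": tun.significant})
        except ValueError as err:
            log.warning("phase analysis skipped for unit %d: %s",
                        u.unit_id, err)
        spk_z = xcorr.bin_and_zscore(u, config.bin_width, duration=duration)
        xc = xcorr.cross_correlate(spk_z, amp_z, config.bin_width,
                                   config.max_lag)
        lag, val = xcorr.peak_lag(xc)
        xc_rows.append({"unit_id": u.unit_id, "peak_lag_s": lag,
                        "peak_value": val})
        if duration >= 60.0:
            coh = spectral.spike_field_coherence(
                u, session.angle.samples, fs, nw=config.taper_nw,
                k=config.taper_k, window=config.spectral_window,
                overlap=config.spectral_overlap)
            null = spectral.shuffle_null_coherence(
                u, session.angle.samples, fs, n_shuffles=config.n_shuffles,
                seed=config.seed + u.unit_id, margin=config.shuffle_margin,
                nw=config.taper_nw, k=config.taper_k,
                window=config.spectral_window,
                overlap=config.spectral_overlap)
            coh_rows.append({
                "unit_id": u.unit_id,
                "coh_low": spectral.band_average(coh.freqs, coh.coherence,
                                                 config.band_low),
                "coh_high": spectral.band_average(coh.freqs, coh.coherence,
                                                  config.band_high),
                "null_low": spectral.band_average(null.freqs,
                                                  null.null_coherence,
                                                  config.band_low),
                "null_high": spectral.band_average(null.freqs,
                                                   null.null_coherence,
                                                   config.band_high),
                "reliable": coh.reliable})

    bundle = {
        "decomposition": dec,
        "whisking_fraction": kinematics.whisking_fraction(dec.state),
        "qc": qc_table,
        "rates": pd.DataFrame(rate_rows),
        "phase": pd.DataFrame(phase_rows),
        "xcorr": pd.DataFrame(xc_rows),
        "coherence": pd.DataFrame(coh_rows),
        "config": config,
        "config_hash": config.content_hash(),
    }
    if session.pupil is not None:
        pup_z = xcorr.bin_and_zscore(session.pupil.diameter,
                                     config.bin_width,
                                     frame_rate=session.pupil.frame_rate)
        xc = xcorr.cross_correlate(amp_z, pup_z, config.bin_width,
                                   config.max_lag)
        lag, val = xcorr.peak_lag(xc)
        bundle["pupil_whisk_lag_s"] = lag
        bundle["pupil_whisk_peak"] = val
    return bundle


def write_results(bundle: dict, outdir) -> None:
    """Write the bundle's tables as CSV with an embedded config header."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: AnalysisConfig = bundle["config"]
    header = "".join(f"# {line}\n" for line in
                     [f"config_hash: {bundle['config_hash']}"]
                     + config.to_yaml().strip().splitlines())
    for name in ("qc", "rates", "phase", "xcorr", "coherence"):
        tab = bundle.get(name)
        if tab is None or tab.empty:
            continue
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            tab.to_csv(fh, index=False)
    summary = {k: bundle[k] for k in
               ("whisking_fraction", "pupil_whisk_lag_s", "pupil_whisk_peak")
               if k in bundle}
    summary["config_hash"] = bundle["config_hash"]
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
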