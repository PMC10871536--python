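"""Shared file I/O: delimited text tables with JSON metadata sidecars.

Dialect is fixed package-wide: comma-separated, header row, "." decimal,
UTF-8, no thousands separators.  Each data file ``foo.csv`` (or ``foo.xyz``)
carries its physical metadata in a sidecar ``foo.json`` next to it.
Temperatures in sidecars may be given as ``T_celsius`` or ``T_K``;
everything is stored in kelvin in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from .datatypes import (
    ChainTrajectory,
    DensityProfile,
    FRAPTrace,
    ModulusSpectrum,
    ParticleTrackSet,
    StressSeries,
    TrapTrajectory,
)

__all__ = [
    "sidecar_path",
    "read_sidecar",
    "write_sidecar",
    "write_trap_trajectory",
    "read_trap_trajectory",
    "write_tracks",
    "read_tracks",
    "write_frap_trace",
    "read_frap_trace",
    "write_spectrum",
    "read_spectrum",
    "write_chain_trajectory",
    "read_chain_trajectory",
    "write_stress_series",
    "read_stress_series",
    "write_density_profile",
    "read_density_profile",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_sidecar(path, meta: dict) -> None:
    sidecar_path(path).write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_sidecar(path) -> dict:
    p = sidecar_path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing metadata sidecar {p}")
    return json.loads(p.read_text(encoding="utf-8"))


def _temperature_K(meta: dict, *, required: bool = True) -> float | None:
    if "T_K" in meta:
        return float(meta["T_K"])
    if "T_celsius" in meta:
        return celsius_to_kelvin(float(meta["T_celsius"]))
    if required:
        raise KeyError("sidecar must provide T_K or T_celsius")
    return None


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


# -- trapped bead ----------------------------------------------------------

def write_trap_trajectory(traj: TrapTrajectory, path) -> None:
    _write_csv(pd.DataFrame({"t_s": traj.t, "x_um": traj.x}), path)
    write_sidecar(
        path, {"kappa_pN_per_um": traj.kappa, "a_um": traj.a, "T_K": traj.T}
    )


def read_trap_trajectory(path) -> TrapTrajectory:
    df = pd.read_csv(path)
    meta = read_sidecar(path)
    for key in ("kappa_pN_per_um", "a_um"):
        if key not in meta:
            raise KeyError(f"trap-trajectory sidecar missing {key!r}")
    return TrapTrajectory(
        t=df["t_s"].to_numpy(),
        x=df["x_um"].to_numpy(),
        kappa=float(meta["kappa_pN_per_um"]),
        a=float(meta["a_um"]),
        T=_temperature_K(meta),
    )


# -- particle tracks -------------------------------------------------------

def write_tracks(ts: ParticleTrackSet, path) -> None:
    df = ts.tracks.copy()
    df["frame"] = df.groupby("particle_id").cumcount()
    out = df[["particle_id", "frame", "t", "x", "y"]].rename(
        columns={"t": "t_s", "x": "x_um", "y": "y_um"}
    )
    _write_csv(out, path)
    write_sidecar(path, {"T_K": ts.T, "a_um": ts.a, "dt_frame_s": ts.dt_frame})


def read_tracks(path) -> ParticleTrackSet:
    df = pd.read_csv(path)
    meta = read_sidecar(path)
    for key in ("a_um", "dt_frame_s"):
        if key not in meta:
            raise KeyError(f"track sidecar missing {key!r}")
    tracks = df.rename(columns={"t_s": "t", "x_um": "x", "y_um": "y"})[
        ["particle_id", "t", "x", "y"]
    ]
    return ParticleTrackSet(
        tracks=tracks,
        T=_temperature_K(meta),
        a=float(meta["a_um"]),
        dt_frame=float(meta["dt_frame_s"]),
    )


# -- FRAP ------------------------------------------------------------------

def write_frap_trace(trace: FRAPTrace, path) -> None:
    _write_csv(pd.DataFrame({"t_s": trace.t, "intensity": trace.I}), path)
    write_sidecar(path, {"i_bleach": trace.i_bleach, "R_bleach_um": trace.R_bleach})


def read_frap_trace(path) -> FRAPTrace:
    df = pd.read_csv(path)
    meta = read_sidecar(path)
    for key in ("i_bleach", "R_bleach_um"):
        if key not in meta:
            raise KeyError(f"FRAP sidecar missing {key!r}")
    return FRAPTrace(
        t=df["t_s"].to_numpy(),
        I=df["intensity"].to_numpy(),
        i_bleach=int(meta["i_bleach"]),
        R_bleach=float(meta["R_bleach_um"]),
    )


# -- modulus spectrum ------------------------------------------------------

def write_spectrum(spec: ModulusSpectrum, path) -> None:
    _write_csv(
        pd.DataFrame(
            {
                "omega_rad_s": spec.omega,
                "G_prime_Pa": spec.G_prime,
                "G_dprime_Pa": spec.G_dprime,
            }
        ),
        path,
    )


def read_spectrum(path) -> ModulusSpectrum:
    df = pd.read_csv(path)
    return ModulusSpectrum(
        omega=df["omega_rad_s"].to_numpy(),
        G_prime=df["G_prime_Pa"].to_numpy(),
        G_dprime=df["G_dprime_Pa"].to_numpy(),
    )


# -- chain trajectories (XYZ-like text) ------------------------------------

def write_chain_trajectory(traj: ChainTrajectory, path) -> None:
    """Frame blocks: bead count, comment line, then N lines of ``x y z``."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, frame in enumerate(traj.coords):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f"frame {i} t_s={i * traj.dt!r}\n")
            for x, y, z in frame:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
    write_sidecar(
        path,
        {
            "dt_s": traj.dt,
            "zeta_pN_s_per_um": traj.zeta,
            "k_spring_pN_per_um": traj.k_spring,
            "T_K": traj.T,
        },
    )


def read_chain_trajectory(path) -> ChainTrajectory:
    meta = read_sidecar(path)
    for key in ("dt_s", "zeta_pN_s_per_um", "k_spring_pN_per_um"):
        if key not in meta:
            raise KeyError(f"chain sidecar missing {key!r}")
    frames = []
    with open(path, encoding="utf-8") as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment
            frame = np.array(
                [fh.readline().split() for _ in range(n)], dtype=float
            )
            frames.append(frame)
    return ChainTrajectory(
        coords=np.stack(frames),
        dt=float(meta["dt_s"]),
        zeta=float(meta["zeta_pN_s_per_um"]),
        k_spring=float(meta["k_spring_pN_per_um"]),
        T=_temperature_K(meta),
    )


# -- stress series ---------------------------------------------------------

def write_stress_series(stress: StressSeries, path) -> None:
    _write_csv(pd.DataFrame({"t_s": stress.t, "sigma_xy_Pa": stress.sigma_xy}), path)
    write_sidecar(path, {"V_m3": stress.V, "T_K": stress.T})


def read_stress_series(path) -> StressSeries:
    df = pd.read_csv(path)
    meta = read_sidecar(path)
    if "V_m3" not in meta:
        raise KeyError("stress sidecar missing 'V_m3'")
    return StressSeries(
        t=df["t_s"].to_numpy(),
        sigma_xy=df["sigma_xy_Pa"].to_numpy(),
        V=float(meta["V_m3"]),
        T=_temperature_K(meta),
    )


# -- density profiles ------------------------------------------------------

def write_density_profile(profile: DensityProfile, path) -> None:
    _write_csv(pd.DataFrame({"z_um": profile.z, "rho_mg_ml": profile.rho}), path)
    write_sidecar(path, {"T_K": profile.T})


def read_density_profile(path) -> DensityProfile:
    df = pd.read_csv(path)
    meta = read_sidecar(path)
    return DensityProfile(
        z=df["z_um"].to_numpy(),
        rho=df["rho_mg_ml"].to_numpy(),
        T=_temperature_K(meta),
    )
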