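"""Delimited-text readers/writers for the analysis input streams."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dimorphism import DimorphismAxis
from .morpho import LandmarkConfiguration
from .nutrition import (
    N_BEHAVIOR_ITEMS,
    BehaviorRecord,
    BodyComposition,
    FFQRecord,
    compute_body_indices,
)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_ffq",
    "read_behavior",
    "read_body",
    "read_truth",
    "write_axis",
    "read_axis",
]


def read_landmarks(path) -> list[LandmarkConfiguration]:
    """Read long-format landmarks (subject_id, label, x, y, z)."""
    df = pd.read_csv(path)
    required = {"subject_id", "label", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"landmark file missing columns: {sorted(required - set(df.columns))}")
    configs = []
    for sid, sub in df.groupby("subject_id", sort=False):
        configs.append(
            LandmarkConfiguration(
                str(sid), sub["label"].astype(str).tolist(), sub[["x", "y", "z"]].to_numpy(float)
            )
        )
    return configs


def write_landmarks(configs: list[LandmarkConfiguration], path) -> None:
    pd.concat([c.as_frame() for c in configs], ignore_index=True).to_csv(path, index=False)


def read_ffq(path) -> list[FFQRecord]:
    """Read the wide FFQ file (amount_*/freq_*/cook_* columns)."""
    df = pd.read_csv(path)
    groups = [c.removeprefix("freq_") for c in df.columns if c.startswith("freq_")]
    cooks = [c.removeprefix("cook_") for c in df.columns if c.startswith("cook_")]
    records = []
    for _, row in df.iterrows():
        records.append(
            FFQRecord(
                subject_id=str(row["subject_id"]),
                amounts={g: str(row[f"amount_{g}"]) for g in groups},
                frequencies={g: float(row[f"freq_{g}"]) for g in groups},
                cooking={k: float(row[f"cook_{k}"]) for k in cooks},
                salt_taste=str(row.get("salt_taste", "lighter")),
            )
        )
    return records


def read_behavior(path, scale_map: list[str] | None = None) -> list[BehaviorRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        responses = {i: int(row[f"item_{i:02d}"]) for i in range(N_BEHAVIOR_ITEMS)}
        kwargs = {} if scale_map is None else {"scale_map": list(scale_map)}
        records.append(BehaviorRecord(str(row["subject_id"]), responses, **kwargs))
    return records


def read_body(path) -> list[BodyComposition]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            compute_body_indices(
                BodyComposition(
                    subject_id=str(row["subject_id"]),
                    weight_kg=float(row["weight_kg"]),
                    height_m=float(row["height_m"]),
                    fat_mass_kg=float(row["fat_mass_kg"]),
                    fat_free_mass_kg=float(row["fat_free_mass_kg"])
                    if "fat_free_mass_kg" in row and pd.notna(row["fat_free_mass_kg"])
                    else None,
                    muscle_mass_kg=float(row["muscle_mass_kg"])
                    if "muscle_mass_kg" in row and pd.notna(row["muscle_mass_kg"])
                    else None,
                )
            )
        )
    return out


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_axis(axis: DimorphismAxis, labels: list[str], path) -> None:
    """Write male/female mean shapes in the landmark long format."""
    p = len(labels)
    male = axis.male_mean.reshape(p, 3)
    female = axis.female_mean.reshape(p, 3)
    frames = []
    for sid, X in (("male_mean", male), ("female_mean", female)):
        frames.append(
            pd.DataFrame(X, columns=["x", "y", "z"]).assign(label=labels, subject_id=sid)
        )
    pd.concat(frames, ignore_index=True)[["subject_id", "label", "x", "y", "z"]].to_csv(
        path, index=False
    )


def read_axis(path) -> tuple[DimorphismAxis, list[str]]:
    df = pd.read_csv(path)
    male = df[df["subject_id"] == "male_mean"]
    female = df[df["subject_id"] == "female_mean"]
    if male.empty or female.empty:
        raise ValueError("axis file must contain male_mean and female_mean shapes")
    labels = male["label"].astype(str).tolist()
    if female["label"].astype(str).tolist() != labels:
        raise ValueError("male and female shapes have mismatched landmark sets")
    return (
        DimorphismAxis(
            male[["x", "y", "z"]].to_numpy(float).ravel(),
            female[["x", "y", "z"]].to_numpy(float).ravel(),
        ),
        labels,
    )
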