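"""Reader-study orchestration: pipelines x readers x repeats -> reliability report.

Reproduces the design of a repeated-measures reader study: every reader
provides several repeats of the manual inputs (seed coordinates, and a
crescent VOI for the comparator method) for every patient; the mirror-image
pipeline runs on each seed set and the guided crescent-shape pipeline on each
(seed set, crescent) pair.  The resulting long-format measurement table feeds
the CoV/ICC reliability report and the paired method comparisons.

Pipeline failures on individual cells are recorded and excluded from the
statistics with a logged count — never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    FetMirrorError,
    SeedSet,
    SUVImage,
    VoxelMask,
    read_mask,
    read_suv_image,
    write_image,
    write_mask,
)
from .gcs import run_gcs
from .mi import MIConfig, run_mi
from .phantom import Phantom, ReaderInput, SimulatedReaderSpec, simulate_reader_inputs
from .stats import reliability_report, validate_reader_table

logger = logging.getLogger(__name__)

__all__ = [
    "PatientCase",
    "StudyResult",
    "run_reader_study",
    "write_phantom_bundle",
    "load_phantom_bundle",
    "load_study_bundles",
]


@dataclass
class PatientCase:
    """One patient's image, brain mask and per-reader-per-repeat manual inputs."""

    patient_id: str
    image: SUVImage
    brain: VoxelMask
    inputs: list[list[ReaderInput]]  # inputs[reader][repeat]


@dataclass
class StudyResult:
    table: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    def report(self) -> dict:
        return reliability_report(self.table)


def run_reader_study(
    patients: list[PatientCase],
    cfg: MIConfig | None = None,
    methods: tuple[str, ...] = ("MI", "gCS"),
) -> StudyResult:
    """Run the requested pipelines over every (patient, reader, repeat) cell."""
    cfg = cfg or MIConfig()
    rows: list[dict] = []
    failures: list[dict] = []

    for case in patients:
        for r, repeats in enumerate(case.inputs):
            reader_id = f"reader_{r + 1}"
            for j, inp in enumerate(repeats):
                cell = {
                    "patient_id": case.patient_id,
                    "reader_id": reader_id,
                    "repeat": j + 1,
                }
                if "MI" in methods:
                    try:
                        res = run_mi(case.image, case.brain, inp.seeds, cfg)
                        if not res.converged:
                            raise FetMirrorError(
                                f"mirror-image run did not converge in {cfg.max_iterations} iterations"
                            )
                        rows.append(
                            cell
                            | {
                                "method": "MI",
                                "ctrl_suv_mean": res.ctrl_suv_mean,
                                "btv_cm3": res.btv_volume_cm3,
                            }
                        )
                    except FetMirrorError as err:
                        failures.append(cell | {"method": "MI", "error": str(err)})
                if "gCS" in methods and inp.crescent is not None:
                    try:
                        res = run_gcs(case.image, case.brain, inp.seeds, inp.crescent, cfg)
                        rows.append(
                            cell
                            | {
                                "method": "gCS",
                                "ctrl_suv_mean": res.ctrl_suv_mean,
                                "btv_cm3": res.btv_volume_cm3,
                            }
                        )
                    except (FetMirrorError, ValueError) as err:
                        failures.append(cell | {"method": "gCS", "error": str(err)})

    if failures:
        logger.warning(
            "%d pipeline cell(s) failed and were excluded from the statistics", len(failures)
        )
    if not rows:
        raise FetMirrorError("every pipeline cell failed; no measurements to report")
    table = validate_reader_table(pd.DataFrame(rows))
    return StudyResult(table=table, failures=failures)


# ---------------------------------------------------------------------------
# Phantom bundle I/O (what the `phantom` and `reader-study` commands exchange)
# ---------------------------------------------------------------------------

def write_phantom_bundle(
    phantom: Phantom,
    outdir: str | Path,
    reader_inputs: list[list[ReaderInput]] | None = None,
    reader_spec: SimulatedReaderSpec | None = None,
) -> Path:
    """Write suv/brain/lesion NIfTIs plus per-reader inputs and a spec echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(phantom.image, outdir / "suv.nii.gz")
    write_mask(phantom.brain, outdir / "brain.nii.gz")
    for i, lesion in enumerate(phantom.true_lesions):
        write_mask(lesion, outdir / f"lesion_{i}.nii.gz")

    if reader_inputs is None and reader_spec is not None:
        reader_inputs = simulate_reader_inputs(phantom, reader_spec)
    if reader_inputs is not None:
        rdir = outdir / "readers"
        rdir.mkdir(exist_ok=True)
        for r, repeats in enumerate(reader_inputs):
            for j, inp in enumerate(repeats):
                stem = f"reader_{r + 1}_rep_{j + 1}"
                inp.seeds.to_json(rdir / f"{stem}_seeds.json")
                if inp.crescent is not None:
                    write_mask(inp.crescent, rdir / f"{stem}_crescent.nii.gz")

    echo = {
        "phantom_spec": {
            "shape": list(phantom.spec.shape),
            "spacing": list(phantom.spec.spacing),
            "brain_semiaxes_mm": list(phantom.spec.brain_semiaxes_mm),
            "background_suv": phantom.spec.background_suv,
            "noise_sd": phantom.spec.noise_sd,
            "rng_seed": phantom.spec.rng_seed,
            "midline_axis": phantom.spec.midline_axis,
            "lesions": [
                {
                    "centre_mm": list(l.centre_mm),
                    "radius_mm": l.radius_mm,
                    "suv": l.suv,
                    "shape": l.shape,
                    "rim_width_mm": l.rim_width_mm,
                    "rim_suv": l.rim_suv,
                }
                for l in phantom.spec.lesions
            ],
        },
        "reader_spec": None if reader_spec is None else vars(reader_spec).copy(),
    }
    with open(outdir / "spec.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
    return outdir


def load_phantom_bundle(bundle_dir: str | Path, midline_axis: int | None = None) -> PatientCase:
    """Load one phantom bundle directory into a :class:`PatientCase`."""
    bundle_dir = Path(bundle_dir)
    spec_path = bundle_dir / "spec.json"
    if midline_axis is None:
        midline_axis = 0
        if spec_path.exists():
            with open(spec_path) as fh:
                midline_axis = json.load(fh).get("phantom_spec", {}).get("midline_axis", 0)
    image = read_suv_image(bundle_dir / "suv.nii.gz", midline_axis=midline_axis)
    brain = read_mask(bundle_dir / "brain.nii.gz")

    inputs: list[list[ReaderInput]] = []
    rdir = bundle_dir / "readers"
    if rdir.is_dir():
        r = 1
        while (rdir / f"reader_{r}_rep_1_seeds.json").exists():
            repeats = []
            j = 1
            while (seed_path := rdir / f"reader_{r}_rep_{j}_seeds.json").exists():
                crescent_path = rdir / f"reader_{r}_rep_{j}_crescent.nii.gz"
                repeats.append(
                    ReaderInput(
                        seeds=SeedSet.from_json(seed_path),
                        crescent=read_mask(crescent_path) if crescent_path.exists() else None,
                    )
                )
                j += 1
            inputs.append(repeats)
            r += 1
    if not inputs:
        raise FileNotFoundError(f"no reader inputs found under {rdir}")
    return PatientCase(
        patient_id=bundle_dir.name, image=image, brain=brain, inputs=inputs
    )


def load_study_bundles(root: str | Path) -> list[PatientCase]:
    """Load a single bundle, or every bundle subdirectory of ``root``."""
    root = Path(root)
    if (root / "suv.nii.gz").exists():
        return [load_phantom_bundle(root)]
    cases = [
        load_phantom_bundle(sub)
        for sub in sorted(root.iterdir())
        if sub.is_dir() and (sub / "suv.nii.gz").exists()
    ]
    if not cases:
        raise FileNotFoundError(f"no phantom bundles found under {root}")
    return cases
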