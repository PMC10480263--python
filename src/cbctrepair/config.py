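"""Run configuration: one YAML document, one global seed, two scale profiles.

The ``desk`` profile (128-px phantoms, 90 projection angles, 16 base
filters, short trainings) runs the whole chain on one CPU in minutes; the
``full`` profile holds the full-scale settings (512 px, 180 angles, 64
filters, 200/500-epoch trainings). Every stage derives its seed
deterministically from the global seed plus a fixed per-stage offset, so a
single integer reproduces a whole run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

STAGE_OFFSETS = {
    "phantom": 101,
    "sim": 211,
    "prep": 307,
    "train": 401,
    "transfer": 503,
    "eval": 601,
}

PROFILES = {
    "desk": {
        "phantom": {"image_size": 128, "n_patients": 3, "slices_per_patient": 8},
        "sim": {"fov_radius": 32.0, "n_angles": 90, "deform_grid_spacing": 16,
                "deform_max_disp": 4.0},
        "prep": {"registration": False},
        "train": {"base_filters": 8, "epochs": 20, "encoder_depth": 6},
        "transfer": {"epochs": 10, "n_trainable_param_layers": 2},
        "eval": {},
    },
    "full": {
        "phantom": {"image_size": 512, "n_patients": 15, "slices_per_patient": 91},
        "sim": {"fov_radius": 128.0, "n_angles": 180, "deform_grid_spacing": 64,
                "deform_max_disp": 15.0},
        "prep": {"registration": True},
        "train": {"base_filters": 64, "epochs": 500, "encoder_depth": 8},
        "transfer": {"epochs": 500, "n_trainable_param_layers": 2},
        "eval": {},
    },
}

_KNOWN_TOP = {"seed", "out_dir", "profile", *STAGE_OFFSETS}


class RunConfig:
    """Validated, profile-expanded configuration document."""

    def __init__(self, doc: dict | None = None):
        doc = dict(doc or {})
        unknown = set(doc) - _KNOWN_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(doc.pop("seed", 0))
        self.out_dir = doc.pop("out_dir", "runs")
        profile = doc.pop("profile", "desk")
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        self.profile = profile
        self.sections = {k: dict(v) for k, v in PROFILES[profile].items()}
        for stage, overrides in doc.items():
            self.sections[stage].update(overrides or {})

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        ss = np.random.SeedSequence([self.seed, STAGE_OFFSETS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def __getitem__(self, stage: str) -> dict:
        return self.sections[stage]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        doc = {"seed": self.seed, "out_dir": self.out_dir, "profile": self.profile,
               **self.sections}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
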