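"""End-to-end study orchestration.

Study A (synthetic proof of concept): simulate streaked, truncated CBCT from
CT, train a streak-removal model (input: simulated CBCT, target: clean CT
under the same field-of-view mask), then train an anatomy-imputation model
whose inputs are the streak model's own outputs and whose targets are the
full clean CT. The two models form a cascade and are trained sequentially.

Study B (clinical-style): build (padded CBCT, registered couch-removed CT)
pairs for a base cohort, train one combined model, then adapt it to a single
held-out patient by transfer learning on that patient's planning CT and one
or two setup CBCT sets ("patient-specific model 1" and "2").

Every run emits a manifest (seeds, splits, configs, data fingerprints) so
seeded reruns are bit-reproducible and train/test leakage is checkable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .gan import Pix2PixGAN
from .phantom import CTVolume
from .prep import PairedSample, build_training_pairs
from .simulate import SimParams, body_mask, sample_isocentre, simulate_scbct_slice


def fingerprint(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, np.float32).tobytes()).hexdigest()


@dataclass
class StudyAConfig:
    sim_params: SimParams = field(default_factory=SimParams)
    streak_train: dict = field(default_factory=dict)  # Pix2PixGAN kwargs
    imputation_train: dict = field(default_factory=dict)
    n_test_patients: int = 1
    seed: int = 0


@dataclass
class StudyBConfig:
    base_train: dict = field(default_factory=dict)
    transfer: dict = field(default_factory=dict)  # transfer_learn kwargs
    prep: dict = field(default_factory=lambda: {"registration": False})
    n_base_patients: int = 15
    transfer_patient_id: str | None = None
    seed: int = 0


def simulate_cbct_volume(
    ct_vol: CTVolume, params: SimParams | None = None, seed: int = 0
) -> tuple[CTVolume, list]:
    """Simulate one setup-CBCT acquisition of a CT volume.

    One isocentre is drawn for the whole acquisition (a real scan rotates
    about a single axis), then every slice is streaked and truncated about
    it. Returns the CBCT volume and the per-slice SimPair records.
    """
    params = params or SimParams()
    mid = ct_vol[len(ct_vol) // 2]
    iso = sample_isocentre(body_mask(mid), params, seed=seed)
    pairs = []
    out = np.empty_like(ct_vol.data)
    for i in range(len(ct_vol)):
        pair = simulate_scbct_slice(ct_vol[i], params, seed=seed * 100003 + i, isocentre=iso)
        pairs.append(pair)
        out[i] = pair.scbct
    vol = CTVolume(out, ct_vol.slice_thickness, patient_id=f"{ct_vol.patient_id}-cbct{seed}")
    return vol, pairs


def run_study_a(ct_dataset: list[CTVolume], config: StudyAConfig):
    """Train the two-model cascade on simulated data.

    Returns (streak_model, imputation_model, manifest). The last
    ``n_test_patients`` volumes form a patient-level holdout.
    """
    if not ct_dataset:
        raise ValueError("empty CT dataset")
    if config.n_test_patients >= len(ct_dataset):
        raise ValueError("holdout would leave no training patients")
    train_vols = ct_dataset[: -config.n_test_patients]
    test_vols = ct_dataset[-config.n_test_patients :]

    def simulate_set(vols, seed0):
        scbct, streak_gt, full_gt, meta = [], [], [], []
        for v, vol in enumerate(vols):
            for i in range(len(vol)):
                p = simulate_scbct_slice(
                    vol[i], config.sim_params, seed=seed0 + v * 10007 + i
                )
                scbct.append(p.scbct)
                streak_gt.append(p.streak_gt)
                full_gt.append(p.full_gt)
                meta.append((vol.patient_id, i, p.replaced_fraction))
        return np.stack(scbct), np.stack(streak_gt), np.stack(full_gt), meta

    tr = simulate_set(train_vols, config.seed)
    te = simulate_set(test_vols, config.seed + 500009)

    streak_model = Pix2PixGAN(input_size=tr[0].shape[1], **config.streak_train)
    streak_model.fit(tr[0], tr[1])

    # the second model's inputs are the first model's outputs, never raw sCBCT
    streak_out = streak_model.predict(tr[0])
    imputation_model = Pix2PixGAN(input_size=tr[0].shape[1], **config.imputation_train)
    imputation_model.fit(streak_out, tr[2])

    manifest = {
        "seed": config.seed,
        "train_patients": [v.patient_id for v in train_vols],
        "test_patients": [v.patient_id for v in test_vols],
        "n_train_pairs": int(tr[0].shape[0]),
        "n_test_pairs": int(te[0].shape[0]),
        "train_fingerprints": [fingerprint(s) for s in tr[0]],
        "test_fingerprints": [fingerprint(s) for s in te[0]],
        "datasets": {
            "train": {"scbct": tr[0], "streak_gt": tr[1], "full_gt": tr[2],
                      "streak_out": streak_out},
            "test": {"scbct": te[0], "streak_gt": te[1], "full_gt": te[2]},
        },
    }
    return streak_model, imputation_model, manifest


def run_study_b_base(
    patients: list[tuple[CTVolume, list[CTVolume]]], config: StudyBConfig
):
    """Train the single combined base model on the multi-patient cohort."""
    if config.transfer_patient_id is not None:
        for ct, _ in patients:
            if ct.patient_id == config.transfer_patient_id:
                raise ValueError(
                    f"transfer patient {config.transfer_patient_id!r} must be "
                    "excluded from the base training cohort"
                )
    all_pairs: list[PairedSample] = []
    for ct, cbcts in patients:
        all_pairs.extend(build_training_pairs(ct, cbcts, config.prep))
    X = np.stack([p.input_img for p in all_pairs])
    y = np.stack([p.target_img for p in all_pairs])
    model = Pix2PixGAN(input_size=X.shape[1], **config.base_train)
    model.fit(X, y)
    manifest = {
        "seed": config.seed,
        "cohort": [ct.patient_id for ct, _ in patients],
        "n_train_pairs": len(all_pairs),
        "train_fingerprints": [fingerprint(p.input_img) for p in all_pairs],
        "config": {k: v for k, v in vars(config).items() if not isinstance(v, SimParams)},
    }
    return model, manifest


def make_patient_specific(
    base_model: Pix2PixGAN,
    patient: tuple[CTVolume, list[CTVolume]],
    n_cbct_sets: int,
    config: StudyBConfig,
):
    """Transfer-learn a patient-specific model from the base model.

    Uses the patient's planning CT and the first ``n_cbct_sets`` setup CBCT
    sets; one set gives 'patient-specific model 1', two give 'model 2'.
    Returns (model, manifest); the base model is left unmodified.
    """
    ct, cbcts = patient
    if n_cbct_sets > len(cbcts):
        raise ValueError(f"patient has only {len(cbcts)} CBCT sets")
    pairs = build_training_pairs(ct, cbcts[:n_cbct_sets], config.prep)
    X = np.stack([p.input_img for p in pairs])
    y = np.stack([p.target_img for p in pairs])
    model = base_model.transfer(X, y, **config.transfer)
    manifest = {
        "label": f"Patient-specific model {n_cbct_sets}",
        "patient": ct.patient_id,
        "n_transfer_pairs": len(pairs),
        "transfer_fingerprints": [fingerprint(p.input_img) for p in pairs],
    }
    return model, manifest


def infer_volume(model: Pix2PixGAN, cbct_vol: CTVolume) -> CTVolume:
    """Slice-wise inference preserving count, order and thickness."""
    out = model.predict(cbct_vol.data)
    return CTVolume(out, cbct_vol.slice_thickness, patient_id=f"{cbct_vol.patient_id}-sct")
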