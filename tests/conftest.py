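"""Shared fixtures: printed worked-example tables and synthetic model fits.

Expensive model fits are session-scoped so the recovery, imbalance and
robustness tests share them instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

from chidt.features import enumerate_candidate_sites, extract_window
from chidt.model import fit
from chidt.simulate import DonorPWM, SimConfig, generate_dataset, make_worked_fixtures, mutate_indels


@pytest.fixture(scope="session")
def worked():
    return make_worked_fixtures()


def windows_of(records, upstream=3, downstream=8, anchor=71):
    return [
        extract_window(seq, anchor, upstream, downstream, lab, origin_id=rid)
        for rid, seq, lab in records
    ]


def reanchored_windows(records, indel_rate, rng, max_shift=5):
    """Mutate full sequences, re-anchor at the GT nearest the original site.

    Emulates candidate re-extraction from frameshift-mutated sequences:
    records whose nearest surviving GT lies more than ``max_shift`` from
    the original anchor are dropped, as their site is effectively lost.
    """
    wins, labs = [], []
    for rid, seq, lab in records:
        if indel_rate:
            seq = mutate_indels(seq, indel_rate, rng=rng)
        best = None
        for site in enumerate_candidate_sites(seq, 3, 8, rid)[0]:
            if best is None or abs(site.gt_position - 71) < abs(best - 71):
                best = site.gt_position
        if best is None or abs(best - 71) > max_shift:
            continue
        wins.append(extract_window(seq, best, 3, 8, lab, origin_id=rid))
        labs.append(lab)
    return wins, labs


@pytest.fixture(scope="session")
def strong_pwm():
    return DonorPWM(sharpness=2.0)


@pytest.fixture(scope="session")
def model_1to50_strong(strong_pwm):
    """Balanced model trained on strong-signal 1:50 data (300/15000)."""
    records = generate_dataset(SimConfig(300, 15000, seed=42), strong_pwm)
    return fit(windows_of(records), balanced=True)


@pytest.fixture(scope="session")
def sweep_models(strong_pwm):
    """Balanced models at 1:1 and 1:100 training imbalance, same positive model."""
    out = {}
    for ratio, n_neg in (("1:1", 300), ("1:100", 30000)):
        records = generate_dataset(SimConfig(300, n_neg, seed=42), strong_pwm)
        out[ratio] = fit(windows_of(records), balanced=True)
    return out


@pytest.fixture(scope="session")
def balanced_test_set(strong_pwm):
    records = generate_dataset(SimConfig(400, 400, seed=7), strong_pwm)
    wins = windows_of(records)
    return wins, [w.label for w in wins]


@pytest.fixture(scope="session")
def small_model(strong_pwm):
    """Quick model for structural checks (exhaustiveness, round-trips)."""
    records = generate_dataset(SimConfig(150, 600, seed=3), strong_pwm)
    return fit(windows_of(records), balanced=True)
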