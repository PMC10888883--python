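import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from metabopipe.models import (
    Annotation,
    EmpiricalCompound,
    Feature,
    FeatureTable,
    MS1Member,
    MSSpectrum,
)


@pytest.fixture
def toy_table():
    """3 features x 2 acquisitions, hand-written values."""
    return FeatureTable(
        features=[
            Feature("F1", 181.0707, 100.0, {"s1": 1000.0, "s2": 1200.0}),
            Feature("F2", 182.0740, 100.2, {"s1": 150.0, "s2": 180.0}),
            Feature("F3", 250.0500, 300.0, {"s1": 5000.0, "s2": 0.0}),
        ],
        acquisitions=["s1", "s2"],
        provenance_tag="toy",
    )


def random_empcpd(rng, idx):
    """A structurally random but invariant-satisfying empirical compound."""
    isotopes = ["M0", "13C/12C", "13C/12C*2", "13C/12C*3"]
    adducts = ["M+H[1+]", "M+Na[1+]", "M+NH4[1+]", "M+K[1+]"]
    cells = [(i, a) for i in isotopes for a in adducts]
    rng.shuffle(cells)
    n_members = rng.integers(1, 6)
    members = [
        MS1Member(
            feature_id=f"F{idx}_{k}",
            isotope=iso,
            modification=mod,
            mz=float(rng.uniform(80, 900)),
            rtime=float(rng.uniform(0, 1200)),
        )
        for k, (iso, mod) in enumerate(cells[:n_members])
    ]
    spectra = []
    for s in range(rng.integers(0, 3)):
        mzs = np.sort(rng.uniform(50, 500, size=rng.integers(3, 8)))
        spectra.append(
            MSSpectrum(
                peaks=[(float(m), float(i)) for m, i in zip(mzs, rng.uniform(0, 1e5, len(mzs)))],
                ms_level=2,
                precursor_mz=float(rng.uniform(100, 900)),
                retention_time=float(rng.uniform(0, 1200)),
                source_acquisition=f"acq{s}",
            )
        )
    annotations = []
    if rng.random() < 0.7:
        annotations.append(
            Annotation(
                level="4",
                compound_name=f"cpd_{idx}",
                identifiers={"formula": "C6H12O6"},
                source="list_a",
                evidence={"ppm_error": float(rng.normal(0, 2))},
            )
        )
    if rng.random() < 0.5:
        annotations.append(
            Annotation(
                level="2",
                compound_name=f"cpd_{idx}_ms2",
                score=float(rng.uniform(0.6, 1.0)),
                source="lib_b",
                evidence={"n_matched_peaks": 4},
            )
        )
    ec = EmpiricalCompound(
        interim_id=f"E{idx:04d}",
        neutral_formula_mass=float(rng.uniform(80, 900)) if rng.random() < 0.8 else None,
        neutral_formula="C6H12O6" if rng.random() < 0.3 else None,
        charge_sign=1 if rng.random() < 0.5 else -1,
        ms1_features=members,
        ms2_spectra=spectra,
    )
    for ann in sorted(annotations, key=lambda a: a.sort_key()):
        ec.add_annotation(ann)
    return ec


@pytest.fixture
def random_empcpds():
    rng = np.random.default_rng(2024)
    return [random_empcpd(rng, i) for i in range(100)]
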