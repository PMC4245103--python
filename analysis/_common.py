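"""Shared configuration for the analysis scripts.

A modest synthetic campaign: 6 post-breeding deployments staggered a week
apart from 1 October, 100 days each, default ocean truth.  Raw records and
rasters go to scratch/ (regenerable); derived tables go to results/.
"""

import datetime as dt
from pathlib import Path

import sealight as sl

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20021126
N_SEALS = 6
N_DAYS = 100
STAGGER_DAYS = 7
START = dt.date(2002, 10, 1)

TRUTH = sl.OceanTruth()


def deployment_specs():
    return [
        sl.DeploymentSpec(
            seal_id=f"seal{i:02d}",
            start_date=START + dt.timedelta(days=STAGGER_DAYS * i),
            n_days=N_DAYS,
            seed=SEED,
        )
        for i in range(N_SEALS)
    ]


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
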