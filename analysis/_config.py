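"""Shared configuration of the numbered analysis scripts.

Every script derives its randomness from ROOT_SEED through named child
seeds, so each step is independently rerunnable and the whole sequence is
reproducible. Small result tables go under results/; bulky raw simulation
output goes under scratch/ (regenerated on demand, never required by a
later step — each script rebuilds its inputs from the same seeds).
"""

import os

from lethalscan import synthetic_data as sd
from lethalscan._seeds import child_seed

ROOT_SEED = 20120829
_HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.normpath(os.path.join(_HERE, "..", "results"))
SCRATCH = os.path.normpath(os.path.join(_HERE, "..", "scratch"))

N_MATINGS_PER_CLASS = 1_000_000  # scale of the insemination-record analysis
POPGEN_SAMPLE = 3038  # size of the genotyped random population sample


def results_dir(name: str) -> str:
    path = os.path.join(RESULTS, name)
    os.makedirs(path, exist_ok=True)
    return path


def scratch_dir(name: str) -> str:
    path = os.path.join(SCRATCH, name)
    os.makedirs(path, exist_ok=True)
    return path


def cohort_genotypes():
    markers = sd.random_marker_map(seed=child_seed(ROOT_SEED, "markers"))
    return sd.simulate_genotypes(
        sd.PopulationConfig(seed=child_seed(ROOT_SEED, "genotypes")), markers
    )


def cohort_reads(genotype: str):
    name = "reads" if genotype == "D/D" else "control_reads"
    return sd.simulate_matepairs(
        sd.ReadSimConfig(seed=child_seed(ROOT_SEED, name)), genotype
    )


def cohort_matings():
    return sd.simulate_matings(
        sd.MatingSimConfig(
            n_per_class=N_MATINGS_PER_CLASS, seed=child_seed(ROOT_SEED, "matings")
        )
    )
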