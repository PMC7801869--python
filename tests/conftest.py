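import numpy as np
import pytest

import tmtopo as t
from tmtopo.synthetic import (
    FamilySimConfig,
    MotifPlanting,
    PlantedAtom,
    ToyStructureConfig,
    build_toy_structure,
    evolve_family,
    spec_for_n_tm,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def family11():
    """An 11-TM family with two planted lumenal motifs (seed-fixed)."""
    cfg = FamilySimConfig(
        n_sequences=6,
        substitution_prob=0.05,
        sprinkle_prob=0.1,
        indel_rate=0.2,
        motifs=(MotifPlanting("SHKSYRP", "EL1", 3),
                MotifPlanting("KETGGT", "EL3", 2)),
        seed=42,
    )
    return evolve_family(spec_for_n_tm(11), cfg)


@pytest.fixture(scope="session")
def family11_result(family11):
    pc = t.PipelineConfig(values={"c_term_side": family11.root_truth.loops[-1][3]})
    return t.run_family_pipeline(family11.sequences, family11.alignment, pc)


@pytest.fixture(scope="session")
def toy_structure(family11):
    truth = family11.root_truth
    h_pos = truth.motif_positions["SHKSYRP"][1]  # the H
    k_pos = truth.motif_positions["KETGGT"][0]
    e_pos = k_pos + 1
    cfg = ToyStructureConfig(
        ligand_atoms=(
            PlantedAtom("C1", "C", h_pos, 4.0),
            PlantedAtom("O1P", "O", k_pos, 3.1, ref="side"),
            PlantedAtom("P1", "P", k_pos, 4.5),
        ),
        ion=PlantedAtom("ZN", "ZN", e_pos, 2.5, ref="side"),
    )
    return build_toy_structure(family11.sequences[0], truth, cfg)
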