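"""Counter-based per-patient random streams.

Every stochastic draw in the simulation comes from a substream keyed by
(root seed, patient id, stream id).  Substreams are independent, and adding
patients to a cohort never perturbs the draws of earlier patients.  Paired
scenario runs re-create shared substreams so both scenarios see identical
death ages and primary-repair failure quantiles (common random numbers);
decision and later failure draws are scenario-specific.
"""

from __future__ import annotations

import numpy as np

# stream ids (selection/perioperative draws are scenario-specific; death and
# failure quantiles are shared between scenarios of a paired run)
DEATH = 0
FAILURE = 1
SELECTION = 2
PERIOP = 3
COHORT = 4
SELECTION_ALT = 6
PERIOP_ALT = 7
FAILURE_ALT = 8
FAILURE_SHARED = 9


def substream(seed: int, patient_id: int, stream: int) -> np.random.Generator:
    """Return the Generator for one (seed, patient, stream) triple.

    Deterministic: the same triple always yields a generator producing the
    same sequence, independent of any other stream.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(patient_id), int(stream)))
    return np.random.default_rng(ss)
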