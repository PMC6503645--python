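import numpy as np
import pytest

import stroketriage as st
from stroketriage.destination_sets import PscOption

# Figure-style worked example: schematic driving times (minutes) for a
# scene with one CSC and two PSCs where both PSCs are admissible.
FIG_A = {"d_csc": 43.0, "psc1": (13.0, 55.0), "psc2": (24.0, 16.0), "dido": 60.0}
# variant where both PSCs lie toward the CSC
FIG_B = {"d_csc": 43.0, "psc1": (19.0, 38.0), "psc2": (34.0, 9.0), "dido": 60.0}


def brute_force_admissible(d_csc, candidates):
    """Independent O(n^2) all-pairs dominance filter for admissible PSCs."""
    kept = []
    for o in candidates:
        if not o.d_psc < d_csc:
            continue
        dominated = any(
            q.d_psc < o.d_psc and q.via_time <= o.via_time for q in candidates
        )
        if not dominated:
            kept.append(o)
    return sorted(kept, key=lambda o: (o.d_psc, o.center_id))


def fig_options(fig):
    (d1, t1), (d2, t2) = fig["psc1"], fig["psc2"]
    return [PscOption("PSC1", d1, t1), PscOption("PSC2", d2, t2)]


def random_point_in_disc(rng, radius):
    r = radius * np.sqrt(rng.random())
    th = rng.random() * 2 * np.pi
    return st.Location(float(r * np.cos(th)), float(r * np.sin(th)))


@pytest.fixture
def env25():
    """Seeded 2-CSC/5-PSC abstract geography on a 30-minute disc."""
    return st.generate_random_environment(2, 5, 30.0, dido=60.0, seed=7)
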