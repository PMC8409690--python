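"""Shared fixtures: the worked-example test and its published weekly table.

PRINTED_TABLE freezes the published 34-week table of the worked example
(sensitivity 0.95, specificity 0.99): week, infected fraction, PPV, zeta
(referenced to the week-14 peak) and PTI, all at the table's own 4-dp print
precision.  The package re-derives PPV/zeta/PTI from the infected column;
these rows are the expected values.

The published PPV/zeta columns were computed from *unrounded* prevalences,
so rows where |dPPV/dphi| > 1 cannot be reproduced exactly from the 4-dp
infected column.  STRICT_PPV_WEEKS / STRICT_ZETA_WEEKS list the rows that
are self-consistent at print precision (desk-verified); the remaining rows
are covered by an interval-consistency check instead.
"""

import pytest
from hypothesis import settings

from screenparadox import TestCharacteristics

# reproducible property tests, independent of any example database
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# (week, infected, ppv, zeta, pti)
PRINTED_TABLE = [
    (1, 0.0001, 0.0094, 0.0095, 3),
    (2, 0.0002, 0.0196, 0.0198, 3),
    (3, 0.0004, 0.0405, 0.0409, 3),
    (4, 0.0009, 0.0816, 0.0824, 3),
    (5, 0.0020, 0.1577, 0.1592, 2),
    (6, 0.0041, 0.2829, 0.2857, 2),
    (7, 0.0087, 0.4541, 0.4585, 2),
    (8, 0.0181, 0.6372, 0.6433, 2),
    (9, 0.0376, 0.7878, 0.7955, 2),
    (10, 0.0766, 0.8874, 0.8960, 2),
    (11, 0.1502, 0.9438, 0.9529, 1),
    (12, 0.2733, 0.9728, 0.9822, 1),
    (13, 0.4289, 0.9862, 0.9957, 1),
    (14, 0.5208, 0.9904, 1.0000, 1),
    (15, 0.4563, 0.9876, 0.9972, 1),
    (16, 0.3281, 0.9789, 0.9884, 1),
    (17, 0.2246, 0.9649, 0.9743, 1),
    (18, 0.1519, 0.9445, 0.9536, 1),
    (19, 0.1022, 0.9154, 0.9242, 1),
    (20, 0.0687, 0.8751, 0.8835, 2),
    (21, 0.0461, 0.8210, 0.8290, 2),
    (22, 0.0309, 0.7517, 0.7590, 2),
    (23, 0.0207, 0.6676, 0.6741, 2),
    (24, 0.0139, 0.5720, 0.5775, 2),
    (25, 0.0093, 0.4713, 0.4758, 2),
    (26, 0.0062, 0.3731, 0.3768, 2),
    (27, 0.0042, 0.2847, 0.2874, 2),
    (28, 0.0028, 0.2102, 0.2123, 2),
    (29, 0.0019, 0.1512, 0.1527, 2),
    (30, 0.0013, 0.1065, 0.1076, 2),
    (31, 0.0008, 0.0739, 0.0747, 3),
    (32, 0.0006, 0.0508, 0.0512, 3),
    (33, 0.0004, 0.0346, 0.0349, 3),
    (34, 0.0003, 0.0234, 0.0236, 3),
]

PEAK_WEEK = 14
PEAK_PREVALENCE = 0.5208

STRICT_PPV_WEEKS = frozenset({1, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 23})
STRICT_ZETA_WEEKS = frozenset({1, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19})


@pytest.fixture(scope="session")
def worked_test() -> TestCharacteristics:
    """The worked example's screening test: sensitivity 0.95, specificity 0.99."""
    return TestCharacteristics(sensitivity=0.95, specificity=0.99)
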