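"""Shared fixtures: the embedded case-study table and its published summary."""

import pytest

from foldplot import fixtures

# Published plot-metrics summary for the wood-frog cyclin dataset:
# (group, variable, fold change, normalized SEM, Tukey letter),
# variable-major, groups in input order.
CYCLIN_METRICS = [
    ("Control", "Cyclin A", 1.0, 0.044782409, "a"),
    ("40% Dehydrated", "Cyclin A", 0.725225991, 0.062004168, "b"),
    ("Rehydrated", "Cyclin A", 1.102725551, 0.041801495, "a"),
    ("Control", "Cyclin B1", 1.0, 0.09349969, "a"),
    ("40% Dehydrated", "Cyclin B1", 0.51947888, 0.119637014, "b"),
    ("Rehydrated", "Cyclin B1", 1.081452203, 0.018013365, "a"),
    ("Control", "Cyclin D1", 1.0, 0.056794487, "a"),
    ("40% Dehydrated", "Cyclin D1", 0.241896859, 0.043813224, "b"),
    ("Rehydrated", "Cyclin D1", 0.673655355, 0.042886507, "c"),
    ("Control", "Cyclin E", 1.0, 0.045240584, "a"),
    ("40% Dehydrated", "Cyclin E", 0.588219496, 0.015748309, "b"),
    ("Rehydrated", "Cyclin E", 0.664993817, 0.024568233, "b"),
]


@pytest.fixture(scope="session")
def cs1():
    return fixtures.casestudy1_table()


@pytest.fixture(scope="session")
def curve_demo():
    return fixtures.curve_demo_table()
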