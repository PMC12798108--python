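import pandas as pd
import pytest

# Published worked example: variety, membership triplet (mu_RPHt, mu_RFW,
# mu_RDW), printed composite D (4 decimals), printed rank.
TABLE2_ROWS = [
    ("P47", (1.0, 1.0, 1.0), 1.0, 1),
    ("P48", (0.6237, 0.8247, 0.3539), 0.6007, 2),
    ("P52", (0.2281, 0.7464, 0.6238), 0.5327, 3),
    ("P15", (0.2986, 0.615, 0.566), 0.4932, 4),
    ("P63", (0.0, 0.6798, 0.3106), 0.3301, 5),
    ("P39", (0.2821, 0.2737, 0.2309), 0.2622, 6),
    ("P6", (0.1977, 0.0625, 0.0454), 0.1019, 7),
    ("P18", (0.1240, 0.0, 0.0), 0.0413, 8),
]


@pytest.fixture(scope="session")
def table2_rows():
    return TABLE2_ROWS


@pytest.fixture
def toy_trait_table():
    """Two accessions x three traits x two conditions, two replicates each."""
    rows = []
    values = {
        ("A1", "PHt", "control"): [20.0, 20.0],
        ("A1", "PHt", "salt"): [18.0, 18.0],
        ("A1", "FW", "control"): [8.0, 8.0],
        ("A1", "FW", "salt"): [6.0, 6.0],
        ("A1", "DW", "control"): [1.0, 1.0],
        ("A1", "DW", "salt"): [0.9, 0.9],
        ("A2", "PHt", "control"): [20.0, 20.0],
        ("A2", "PHt", "salt"): [10.0, 10.0],
        ("A2", "FW", "control"): [8.0, 8.0],
        ("A2", "FW", "salt"): [2.0, 2.0],
        ("A2", "DW", "control"): [1.0, 1.0],
        ("A2", "DW", "salt"): [0.2, 0.2],
    }
    for (acc, trait, cond), reps in values.items():
        for i, v in enumerate(reps, start=1):
            rows.append((acc, trait, cond, i, v))
    return pd.DataFrame(
        rows, columns=["accession", "trait", "condition", "replicate", "value"]
    )
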