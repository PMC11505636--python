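import numpy as np
import pytest

from icrkit import ITEM_IDS, PatientRecord, ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.default()


def make_random_records(n: int, seed: int, with_cariogram: bool = False):
    """Random valid patient records, independent of the simulator."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        levels = {item: int(rng.integers(0, 4)) for item in ITEM_IDS}
        chance = float(rng.uniform(0, 100)) if with_cariogram else None
        records.append(
            PatientRecord(
                patient_id=f"r{i}",
                age_years=float(rng.uniform(6, 12)),
                sex=str(rng.choice(["F", "M"])),
                item_levels=levels,
                cariogram_chance=chance,
            )
        )
    return records
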