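import random
from datetime import datetime, timezone

import pytest

from cellver import codec, repo


@pytest.fixture
def toy_spec():
    """16-bit payload spec: small enough for exhaustive arguments."""
    return codec.BarcodeSpec(payload_bits=16, checksum_bits=16, seed_bits=8)


@pytest.fixture
def default_spec():
    return codec.BarcodeSpec()


@pytest.fixture
def make_store(tmp_path):
    """Factory for deterministic stores (seeded rng, frozen clock)."""

    counter = {"n": 0}

    def _make(seed: int = 1, **kwargs) -> repo.Store:
        counter["n"] += 1
        return repo.Store(
            tmp_path / f"store{counter['n']}",
            rng=random.Random(seed),
            clock=lambda: datetime(2024, 1, 1, 12, 0, 0, tzinfo=timezone.utc),
            **kwargs,
        )

    return _make


@pytest.fixture
def store(make_store):
    return make_store()
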