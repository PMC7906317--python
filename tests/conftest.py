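import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mr2s import HarmonizedInstrument, InstrumentSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_instruments():
    """Factory: instrument set from effect arrays (defaults keep SEs simple)."""

    def _make(bx, by, sx=None, sy=None, eaf=None, label="test"):
        bx = np.asarray(bx, dtype=float)
        by = np.asarray(by, dtype=float)
        sx = np.full(bx.shape, 0.01) if sx is None else np.asarray(sx, dtype=float)
        sy = np.full(bx.shape, 0.1) if sy is None else np.asarray(sy, dtype=float)
        eaf = np.full(bx.shape, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
        return InstrumentSet(
            label=label,
            instruments=tuple(
                HarmonizedInstrument(
                    variant_id=f"rs{i:04d}",
                    beta_exposure=float(bx[i]),
                    se_exposure=float(sx[i]),
                    beta_outcome=float(by[i]),
                    se_outcome=float(sy[i]),
                    eaf=float(eaf[i]),
                )
                for i in range(bx.size)
            ),
        )

    return _make
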