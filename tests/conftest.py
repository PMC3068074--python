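import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "psakit",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("psakit")

from psakit import PSAMeasurement, PSASeries, KineticsWindow, TimeUnit


def make_window(days, values, unit=TimeUnit.DAYS, origin=dt.date(2010, 1, 1)):
    """Kinetics window from day offsets and PSA values."""
    ms = tuple(
        PSAMeasurement(date=origin + dt.timedelta(days=int(d)), psa=float(v))
        for d, v in zip(days, values)
    )
    return KineticsWindow(ms, unit)


def make_series(patient_id, days, values, origin=dt.date(2010, 1, 1)):
    return PSASeries(
        patient_id=patient_id,
        measurements=[
            PSAMeasurement(date=origin + dt.timedelta(days=int(d)), psa=float(v))
            for d, v in zip(days, values)
        ],
    )


@pytest.fixture
def toy_graph_file(tmp_path):
    """Two-branch toy guideline: entry -> therapy A (psa > 20) | therapy B (psa <= 20)."""
    p = tmp_path / "toy.yaml"
    p.write_text(
        """
entry: entry
facts:
  psa: number
nodes:
  - {id: entry, label: Entry, kind: decision, predicate: true}
  - {id: therapyA, label: Therapy A, kind: therapy, predicate: psa > 20}
  - {id: therapyB, label: Therapy B, kind: therapy, predicate: psa <= 20}
edges:
  - {from: entry, to: therapyA}
  - {from: entry, to: therapyB}
""",
        encoding="utf-8",
    )
    return p
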