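import numpy as np
import pandas as pd
import pytest

from nodetrans.kinematics import AnalysisConfig
from nodetrans.track_io import AxonGeometry, Track, project_to_axis


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def straight_geom():
    """100 μm straight axon along x, node at arclength 50, distal = +x."""
    return AxonGeometry(
        centerline=np.array([[0.0, 0.0], [100.0, 0.0]]),
        node_center_arclength=50.0,
        distal_sign=1,
    )


def make_track(x, y=None, dt=0.5, track_id="t0", organelle="endosome", **kw):
    """Track helper: positions in μm, uniform frame interval ``dt``."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    n = len(x)
    return Track(
        track_id=track_id,
        organelle_class=organelle,
        frames=np.arange(n),
        t=np.arange(n) * dt,
        x=x,
        y=y,
        **kw,
    )


def make_axial(s_values, geom, dt=0.5, **kw):
    """Axial track on a straight geometry from node-centred positions."""
    s = np.asarray(s_values, dtype=float)
    tr = make_track(geom.node_center_arclength + geom.distal_sign * s, dt=dt, **kw)
    return project_to_axis(tr, geom)


def steps_frame(speeds, s_mid=0.0, dt=0.5, threshold=0.1, track_id="t0",
                gaps=None):
    """Hand-built step table with the column layout of compute_step_records."""
    speeds = np.asarray(speeds, dtype=float)
    n = len(speeds)
    s_mid = np.broadcast_to(np.asarray(s_mid, dtype=float), (n,))
    gaps = np.zeros(n, bool) if gaps is None else np.asarray(gaps, bool)
    return pd.DataFrame(
        {
            "animal_id": "a0",
            "axon_id": "ax0",
            "track_id": track_id,
            "organelle": "endosome",
            "frame_from": np.arange(n),
            "frame_to": np.arange(1, n + 1),
            "dt": dt,
            "displacement_2d": speeds * dt,
            "speed": speeds,
            "axial_delta": -speeds * dt,
            "s_mid": s_mid,
            "is_pause": speeds <= threshold,
            "is_gap": gaps,
        }
    )
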