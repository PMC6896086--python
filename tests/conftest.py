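import numpy as np
import pytest

import spherotrack as st


@pytest.fixture(scope="session")
def rendered_movie():
    """A clean 10-cell movie with ground truth, shared across tests.

    Cells start on a well-separated grid (spacing 80 px) so detection and
    tracking preconditions (separation, SNR) hold throughout.
    """
    n_cells, n_frames = 10, 30
    shape = (240, 440)  # (h, w)
    starts = np.array([[40 + 80 * (i % 5), 60 + 120 * (i // 5)]
                       for i in range(n_cells)], dtype=float)
    tracks = st.simulate_prw_tracks(n_cells, n_frames, speed=2.0,
                                    turn_sd=0.3,
                                    arena=(shape[1] - 1, shape[0] - 1),
                                    seed=42, start_positions=starts)
    spec = st.SyntheticMovieSpec(frame_shape=shape, hot_pixel_rate=0.0005)
    stack = st.render_movie(tracks, spec, seed=43)
    return tracks, spec, stack


def match_to_truth(detections, truth_tracks, max_dist=3.0):
    """Map each detection row to the nearest true cell (or -1)."""
    pos = truth_tracks.positions
    ids = np.full(len(detections), -1, dtype=int)
    for k, (_, row) in enumerate(detections.iterrows()):
        d = np.hypot(pos[:, int(row.frame), 0] - row.x,
                     pos[:, int(row.frame), 1] - row.y)
        if d.min() <= max_dist:
            ids[k] = int(d.argmin())
    return ids
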