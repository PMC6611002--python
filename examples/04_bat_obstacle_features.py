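"""Obstacle-passage feature vectors for high-speed 3-D flight tracks.

Three toy flights pass a vertical chain array. For each flight, eleven
kinematic and obstacle-relative features are evaluated 0.3/0.2/0.1 s before
and while passing the array plane, giving the 42-column flight table.
"""

import numpy as np

import steftr
from steftr.bat import ObstacleArray, bat_feature_vector

frame_rate = 125.0
t = np.arange(0.0, 1.2, 1.0 / frame_rate)
flights = []
for k, (speed, lateral) in enumerate([(3.5, 0.25), (4.0, 0.05), (4.4, -0.2)]):
    x = -2.5 + speed * t
    y = lateral + 0.1 * np.sin(2 * np.pi * t)  # gentle weaving
    z = 1.5 + 0.05 * np.cos(2 * np.pi * t)
    flights.append(steftr.Trajectory(f"flight{k}", t, np.column_stack([x, y]), z=z))

chains = ObstacleArray(
    np.array([[0.0, y, z] for y in (-0.6, -0.2, 0.2, 0.6) for z in (1.0, 1.4, 1.8)])
)
table = bat_feature_vector(flights, chains)

feature_cols = [c for c in table.columns if c not in ("flight_id", "segment")]
print(f"flights x features : {table.shape[0]} x {len(feature_cols)}")
for _, row in table.iterrows():
    print(
        f"  {row['flight_id']}: V at passage = {row['V_t0']:.2f} m/s, "
        f"nearest chain {row['R_obs_t0']:.2f} m, lateral offset {row['R_y_t0']:.2f} m"
    )
# R_obs is the 3-D distance to the nearest chain edge point at the moment of
# passage; R_y is the lateral distance to the nearest chain.
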