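"""Independent brute-force oracles: hand-rolled 3x3 rotation-matrix algebra.

Deliberately avoids scipy.spatial.transform (the implementation's path):
quaternion -> matrix by the textbook formula, axis-angle matrices by
Rodrigues' formula, and Euler extraction from matrix elements derived from
the symbolic product Ry(a) @ Rx(b) @ Rz(c).
"""

import numpy as np


def quat_to_matrix(w, x, y, z):
    n = np.sqrt(w * w + x * x + y * y + z * z)
    w, x, y, z = w / n, x / n, y / n, z / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def axis_angle_matrix(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def matrix_to_yxz(m):
    """Intrinsic Y-X-Z Euler angles (deg) from M = Ry(a) @ Rx(b) @ Rz(c).

    From the symbolic product: M[1,2] = -sin(b), M[0,2] = sin(a) cos(b),
    M[2,2] = cos(a) cos(b), M[1,0] = cos(b) sin(c), M[1,1] = cos(b) cos(c).
    """
    b = np.arcsin(np.clip(-m[1, 2], -1.0, 1.0))
    a = np.arctan2(m[0, 2], m[2, 2])
    c = np.arctan2(m[1, 0], m[1, 1])
    return np.degrees([a, b, c])


def anatomical_from_matrix(m):
    """(flexion_extension, lateral_flexion, rotation) via the sign map."""
    yaw, pitch, roll = matrix_to_yxz(m)
    return np.array([-pitch, roll, -yaw])
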