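"""Published validation counts for the 2017-2019 Northeast China crop maps.

These are the ground-truth confusion matrices released with the map
product (map classes as rows, reference classes as columns, class order
rice / maize / soybean / other). They are input data for the assessment
module, used to reproduce the product's reported accuracy figures.
"""

import numpy as np

from .assessment import CLASS_ORDER  # noqa: F401  (documents the axis order)

PUBLISHED_CONFUSION = {
    2017: np.array([
        [868, 101, 9, 20],
        [15, 1783, 65, 441],
        [17, 126, 2210, 469],
        [44, 81, 180, 1660],
    ], dtype=np.int64),
    2018: np.array([
        [1206, 11, 1, 39],
        [9, 2241, 67, 667],
        [3, 121, 2197, 864],
        [46, 86, 131, 2974],
    ], dtype=np.int64),
    2019: np.array([
        [1092, 57, 3, 16],
        [5, 2380, 39, 419],
        [6, 111, 2282, 324],
        [53, 229, 203, 3821],
    ], dtype=np.int64),
}
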