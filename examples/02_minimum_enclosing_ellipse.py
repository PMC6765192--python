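"""Minimum enclosing ellipse and the derived path-shape features.

The four corners of a 4x2 rectangle have the closed-form minimum-area
enclosing ellipse a = 2*sqrt(2), b = sqrt(2); eccentricity sqrt(3)/2.
"""

import math

import numpy as np

from zebranvu import WellGeometry, eccentricity, min_enclosing_ellipse, mpdc, mpde

pts = np.array([[2.0, 1.0], [2.0, -1.0], [-2.0, 1.0], [-2.0, -1.0]])
fit = min_enclosing_ellipse(pts)

print(f"semi-axes        : a = {fit.a:.4f} (exact {2 * math.sqrt(2):.4f}), "
      f"b = {fit.b:.4f} (exact {math.sqrt(2):.4f})")
print(f"eccentricity ε   : {eccentricity(fit):.4f} (exact {math.sqrt(3) / 2:.4f})")
print(f"MPDE             : {mpde(pts, fit):.4f} mm (exact {math.sqrt(5):.4f})")
print(f"MPDC (well @ 0,0): {mpdc(pts, WellGeometry()):.4f} mm")

# ε near 1 = elongated path (exploratory swimming along a line);
# ε near 0 = isotropic path. MPDC near the well radius = thigmotaxis.
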