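"""Annotate a small peak list against the built-in species registry.

Builds peaks at known protonated PC masses plus one decoy, annotates them
with a 0.5 Da imaging-mode tolerance window, and prints the match table.
The `ppm` column is the mass error with the observed m/z in the
denominator; the decoy stays unannotated.
"""

import numpy as np

from lipidkit import PeakList, Tolerance, annotate_peaks, default_registry
from lipidkit.annotate import annotations_to_frame
from lipidkit.registry import POSITIVE_ADDUCTS

registry = default_registry()
# observed m/z: PC 32:0 +H, PC 34:1 +H (each 1 mDa high), and a decoy
peaks = PeakList("+", np.array([720.0, 734.5704, 760.5861]),
                 np.array([1.0, 80.0, 100.0]))

annotations = annotate_peaks(peaks, registry, POSITIVE_ADDUCTS, Tolerance.imaging())
print(annotations_to_frame(peaks, annotations).to_string(index=False))
# A matched row shows e.g. species PC 32:0 at delta ~1 mDa (~1.4 ppm);
# the 720.0 peak has no candidate within 0.5 Da and stays blank.
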