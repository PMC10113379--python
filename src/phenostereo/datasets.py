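"""Published worked-example inputs bundled for demos, tests and reports.

These are the printed field measurements that the arithmetic of the pipeline
is expected to reproduce: an RTK-GNSS shooting sequence from a fake-plant
trial flown at 10-20 m, and the disparity / height readings of both that
trial and a buckwheat-field trial flown at 4.1 m.  They are inputs (numbers a
field operator would read off the instrument), not fitted constants.
"""

from __future__ import annotations

from .geodesy import GeoPosition

__all__ = [
    "EXAMPLE_SHOOTING_SEQUENCE",
    "FAKE_PLANT_TRIAL",
    "BUCKWHEAT_TRIAL",
]

#: Seven consecutive RTK-GNSS fixes of a shooting sequence (decimal degrees,
#: printed at 8 decimals latitude / 7 decimals longitude, i.e. ~1 mm / ~9 mm
#: quantisation at this latitude).
EXAMPLE_SHOOTING_SEQUENCE: list[GeoPosition] = [
    GeoPosition(1, 36.11878417, 140.0937983),
    GeoPosition(2, 36.11878317, 140.0937943),
    GeoPosition(3, 36.11878233, 140.0937910),
    GeoPosition(4, 36.11878133, 140.0937872),
    GeoPosition(5, 36.11878050, 140.0937835),
    GeoPosition(6, 36.11877983, 140.0937805),
    GeoPosition(7, 36.11877867, 140.0937767),
]

#: Fake-plant trial, ~18.7 m altitude.  Disparity-map intensities read at the
#: plant top and surrounding ground, the hand-measured heights of the two
#: fake plants, and the height errors (cm) of this method and of the two
#: structure-from-motion packages run on the same flight.
FAKE_PLANT_TRIAL = {
    "plant_disparity": 1224,
    "ground_disparity": 1188,
    "reported_disparity_difference": 37,  # printed value; raw arithmetic gives 36
    "plant_heights_m": (0.240, 0.595),
    "measured_height_m": 0.561,
    "errors_cm": {"stereo": 3.4, "pix4dmapper": 9.0, "metashape": 11.1},
}

#: Buckwheat-field trial, 4.1 m altitude, baseline 0.81 m, two image pairs of
#: different baseline length, plus the comparative errors (cm).
BUCKWHEAT_TRIAL = {
    "short_baseline": {"plant_disparity": 1573, "ground_disparity": 1374},
    "long_baseline": {"plant_disparity": 2320, "ground_disparity": 1957},
    "plant_height_m": 0.570,
    "errors_cm": {"stereo": 5.0, "pix4dmapper": 9.0, "metashape": 13.5},
}
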