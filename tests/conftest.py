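import numpy as np
import pytest

from whalemorph import photogrammetry as pg


@pytest.fixture
def flight():
    return pg.FlightMeta(
        platform_id="P4S",
        altitude=37.5,
        focal_length=8.8,
        sensor_width=13.2,
        image_width=5472,
        image_height=3648,
        altimeter_source="laser",
    )


@pytest.fixture
def simple_flight():
    # GSD of exactly 0.1 m/px for readable arithmetic
    return pg.FlightMeta("simple", altitude=100.0, focal_length=10.0,
                         sensor_width=10.0, image_width=1000)


def make_record(whale="w1", image="i1", flight=None, tl_px=220.0,
                quality=None, is_calf=False, widths_px=None, **extra_px):
    flight = flight or pg.FlightMeta("simple", 100.0, 10.0, 10.0, 1000)
    lengths = {"TL": tl_px, "RB": 0.15 * tl_px, "JL": 0.2 * tl_px,
               "EE": 0.1 * tl_px, "Tail": 0.26 * tl_px, "Fs": 0.22 * tl_px,
               "Fw": 0.07 * tl_px}
    lengths.update(extra_px)
    if widths_px is None:
        widths_px = np.full(19, 0.1 * tl_px)
    return pg.MorphoRecord(
        whale_id=whale, image_id=image, flight=flight, lengths_px=lengths,
        widths_px=widths_px, quality=quality or {k: 1 for k in lengths},
        is_calf=is_calf, population="ENP",
    )
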