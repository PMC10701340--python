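"""Metric morphology from drone image digitizations.

A digitized whale image carries pixel measurements of total length (TL,
rostrum tip to fluke notch), skull metrics (rostrum-to-blowhole RB, jaw
length JL, eye-to-eye EE), fluke/tail metrics (Tail, fluke span Fs, fluke
width Fw) and perpendicular body widths at 5% increments of TL.  This
module converts pixels to meters via the ground sampling distance,
computes the body area index (BAI, a scale-free body-condition metric),
standardizes part lengths by TL, and applies the quality filters used
before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: measurement labels for simple length metrics, in conventional order
LENGTH_MEASUREMENTS = ("TL", "RB", "JL", "EE", "Tail", "Fs", "Fw")

#: part measurements standardized by TL
STANDARDIZED_MEASUREMENTS = ("RB", "JL", "EE", "Tail", "Fs")

#: body-axis width stations as fractions of TL (5%, 10%, ..., 95%)
WIDTH_STATIONS = np.round(np.arange(1, 20) * 0.05, 2)

#: default head-tail range over which BAI integrates the body widths
DEFAULT_BAI_RANGE = (0.20, 0.90)


class InvalidFlightMetadata(ValueError):
    """Flight metadata violates a positivity constraint."""


class IncompleteRecord(ValueError):
    """A width station required by the requested BAI range is missing."""


@dataclass(frozen=True)
class FlightMeta:
    """Camera and altitude metadata for one UAS image.

    altitude is meters above the subject; focal_length and sensor_width
    in millimeters; image_width/height in pixels; altimeter_source is
    ``"barometer"`` or ``"laser"``.
    """

    platform_id: str
    altitude: float
    focal_length: float
    sensor_width: float
    image_width: int
    image_height: int = 0
    altimeter_source: str = "laser"

    def __post_init__(self) -> None:
        if not (
            self.altitude > 0
            and self.focal_length > 0
            and self.sensor_width > 0
            and self.image_width >= 1
        ):
            raise InvalidFlightMetadata(
                f"nonpositive flight metadata for platform {self.platform_id!r}: "
                f"altitude={self.altitude}, focal={self.focal_length}, "
                f"sensor={self.sensor_width}, image_width={self.image_width}"
            )


@dataclass
class MorphoRecord:
    """One whale-image digitization in pixel units.

    ``lengths_px`` maps measurement label -> pixel length (NaN allowed for
    missing); ``widths_px`` holds up to 19 perpendicular widths indexed by
    the 5% stations (NaN where not digitized); ``quality`` maps
    measurement label -> score in {1 (good), 2 (medium), 3 (poor)}.
    """

    whale_id: str
    image_id: str
    flight: FlightMeta
    lengths_px: dict[str, float]
    widths_px: np.ndarray
    quality: dict[str, int] = field(default_factory=dict)
    is_calf: bool = False
    population: str = ""

    def __post_init__(self) -> None:
        self.widths_px = np.asarray(self.widths_px, dtype=float)
        if self.widths_px.shape != (19,):
            raise ValueError(
                f"widths must have 19 stations (5%..95%), got {self.widths_px.shape}"
            )
        bad = {k: v for k, v in self.quality.items() if v not in (1, 2, 3)}
        if bad:
            raise ValueError(f"quality scores must be in {{1,2,3}}: {bad}")


@dataclass
class MetricMorphology:
    """Morphology of one whale (or image) in meters.

    ``standardized`` holds RB/TL, JL/TL, EE/TL, Tail/TL, Fs/TL as
    fractions of total length; BAI is unitless.
    """

    whale_id: str
    lengths_m: dict[str, float]
    widths_m: np.ndarray
    bai: float
    standardized: dict[str, float]
    population: str = ""


def ground_sampling_distance(flight: FlightMeta) -> float:
    """Meters on the subject plane per image pixel.

    GSD = altitude * (sensor_width / focal_length) / image_width; the
    sensor-to-focal ratio converts altitude to the ground footprint of
    the sensor, divided across the pixel columns.
    """
    return flight.altitude * (flight.sensor_width / flight.focal_length) / flight.image_width


def pixels_to_meters(length_px: float, flight: FlightMeta) -> float:
    """Convert a pixel length in ``flight``'s image to meters."""
    if length_px < 0:
        raise ValueError(f"pixel length must be >= 0, got {length_px}")
    return length_px * ground_sampling_distance(flight)


def compute_bai(
    tl: float,
    widths_m: np.ndarray,
    head_tail_range: tuple[float, float] = DEFAULT_BAI_RANGE,
) -> float:
    """Body area index over a head-tail range of the body axis.

    The dorsal surface area SA is the trapezoidal integral of the width
    profile along the body axis from ``head_tail_range[0]*TL`` to
    ``head_tail_range[1]*TL`` (stations every 0.05*TL), and

        BAI = 100 * SA / ((range_fraction * TL))**2

    which is invariant under uniform rescaling of TL and all widths.

    Parameters
    ----------
    tl : total length in meters (> 0).
    widths_m : 19 perpendicular widths in meters at stations 5%..95% of
        TL; stations outside the head-tail range may be NaN.
    head_tail_range : endpoints as fractions of TL, multiples of 0.05;
        default (0.20, 0.90).
    """
    if tl <= 0:
        raise ValueError(f"TL must be positive, got {tl}")
    lo, hi = head_tail_range
    if not (0 < lo < hi < 1):
        raise ValueError(f"invalid head-tail range {head_tail_range}")
    widths_m = np.asarray(widths_m, dtype=float)
    if widths_m.shape != (19,):
        raise ValueError("expected 19 width stations")
    i_lo = int(round(lo / 0.05)) - 1
    i_hi = int(round(hi / 0.05)) - 1
    if not (np.isclose(lo, (i_lo + 1) * 0.05) and np.isclose(hi, (i_hi + 1) * 0.05)):
        raise ValueError("head-tail range endpoints must be multiples of 5%")
    segment = widths_m[i_lo : i_hi + 1]
    if np.isnan(segment).any():
        missing = WIDTH_STATIONS[i_lo : i_hi + 1][np.isnan(segment)]
        raise IncompleteRecord(f"missing width stations at {missing.tolist()} of TL")
    sa = np.trapezoid(segment, dx=0.05 * tl)
    span = (hi - lo) * tl
    return 100.0 * sa / span**2


def standardize_by_tl(lengths_m: dict[str, float]) -> dict[str, float]:
    """Divide each part measurement (RB, JL, EE, Tail, Fs) by TL."""
    tl = lengths_m.get("TL", np.nan)
    if not tl > 0:
        raise ValueError(f"TL must be positive to standardize, got {tl}")
    return {
        name: lengths_m[name] / tl
        for name in STANDARDIZED_MEASUREMENTS
        if name in lengths_m and np.isfinite(lengths_m[name])
    }


def to_metric(record: MorphoRecord, head_tail_range=DEFAULT_BAI_RANGE) -> MetricMorphology:
    """Convert one pixel-space record to metric morphology with BAI."""
    gsd = ground_sampling_distance(record.flight)
    lengths_m = {k: v * gsd for k, v in record.lengths_px.items() if np.isfinite(v)}
    widths_m = record.widths_px * gsd
    bai = compute_bai(lengths_m["TL"], widths_m, head_tail_range)
    return MetricMorphology(
        whale_id=record.whale_id,
        lengths_m=lengths_m,
        widths_m=widths_m,
        bai=bai,
        standardized=standardize_by_tl(lengths_m),
        population=record.population,
    )


def filter_records(
    records: list[MorphoRecord],
    max_images_per_whale: int = 5,
) -> tuple[list[MorphoRecord], pd.DataFrame]:
    """Apply the pre-analysis filters and return (retained, audit log).

    Filters, in order:

    1. drop records of known calves;
    2. per measurement, drop (set to NaN) any value whose quality score
       is 3 (poor); a record losing its TL is dropped entirely since
       nothing downstream can use it;
    3. cap images per whale at ``max_images_per_whale``, keeping the
       best records by mean quality score (lower is better), ties broken
       by input order.

    The audit log records every exclusion with a reason; the function is
    idempotent and never increases the record count.
    """
    audit: list[dict] = []
    retained: list[tuple[int, MorphoRecord]] = []

    for idx, rec in enumerate(records):
        if rec.is_calf:
            audit.append(
                {"whale_id": rec.whale_id, "image_id": rec.image_id,
                 "measurement": "*", "reason": "calf"}
            )
            continue
        lengths = dict(rec.lengths_px)
        quality = dict(rec.quality)
        widths = rec.widths_px.copy()
        for name, score in rec.quality.items():
            if score == 3 and name in lengths and np.isfinite(lengths[name]):
                lengths[name] = np.nan
                audit.append(
                    {"whale_id": rec.whale_id, "image_id": rec.image_id,
                     "measurement": name, "reason": "quality_3"}
                )
        if (quality.get("widths") == 3 or quality.get("BAI") == 3) and np.isfinite(widths).any():
            widths = np.full(19, np.nan)
            audit.append(
                {"whale_id": rec.whale_id, "image_id": rec.image_id,
                 "measurement": "widths", "reason": "quality_3"}
            )
        if not np.isfinite(lengths.get("TL", np.nan)):
            audit.append(
                {"whale_id": rec.whale_id, "image_id": rec.image_id,
                 "measurement": "TL", "reason": "no_usable_TL"}
            )
            continue
        retained.append(
            (idx, replace(rec, lengths_px=lengths, widths_px=widths))
        )

    # cap images per whale: best mean quality first, then input order
    by_whale: dict[str, list[tuple[int, MorphoRecord]]] = {}
    for idx, rec in retained:
        by_whale.setdefault(rec.whale_id, []).append((idx, rec))
    final: list[tuple[int, MorphoRecord]] = []
    for whale, recs in by_whale.items():
        ranked = sorted(
            recs,
            key=lambda pair: (
                float(np.mean(list(pair[1].quality.values()))) if pair[1].quality else 2.0,
                pair[0],
            ),
        )
        for idx, rec in ranked[max_images_per_whale:]:
            audit.append(
                {"whale_id": rec.whale_id, "image_id": rec.image_id,
                 "measurement": "*", "reason": "image_cap"}
            )
        final.extend(ranked[:max_images_per_whale])

    final.sort(key=lambda pair: pair[0])
    audit_df = pd.DataFrame(audit, columns=["whale_id", "image_id", "measurement", "reason"])
    return [rec for _, rec in final], audit_df


def records_from_csv(path) -> list[MorphoRecord]:
    """Read a tidy digitization CSV into MorphoRecord objects.

    Expected columns (CollatriX-style long format): whale_id, image_id,
    population, is_calf, platform_id, altitude, focal_length,
    sensor_width, image_width, image_height, altimeter_source,
    measurement, value_px, quality.  Width rows use measurement labels
    ``W05`` .. ``W95``.
    """
    df = pd.read_csv(path)
    records = []
    for (whale, image), grp in df.groupby(["whale_id", "image_id"], sort=False):
        meta = grp.iloc[0]
        flight = FlightMeta(
            platform_id=str(meta["platform_id"]),
            altitude=float(meta["altitude"]),
            focal_length=float(meta["focal_length"]),
            sensor_width=float(meta["sensor_width"]),
            image_width=int(meta["image_width"]),
            image_height=int(meta.get("image_height", 0)),
            altimeter_source=str(meta.get("altimeter_source", "laser")),
        )
        lengths: dict[str, float] = {}
        quality: dict[str, int] = {}
        widths = np.full(19, np.nan)
        for _, row in grp.iterrows():
            name = str(row["measurement"])
            if name.startswith("W") and name[1:].isdigit():
                widths[int(name[1:]) // 5 - 1] = float(row["value_px"])
            else:
                lengths[name] = float(row["value_px"])
                if "quality" in row and pd.notna(row["quality"]):
                    q = row["quality"]
                    if q not in (1, 2, 3):
                        raise ValueError(
                            f"corrupt quality score {q!r} for {whale}/{image}/{name}"
                        )
                    quality[name] = int(q)
        records.append(
            MorphoRecord(
                whale_id=str(whale),
                image_id=str(image),
                flight=flight,
                lengths_px=lengths,
                widths_px=widths,
                quality=quality,
                is_calf=bool(meta.get("is_calf", False)),
                population=str(meta.get("population", "")),
            )
        )
    return records


def metric_table(morphs: list[MetricMorphology]) -> pd.DataFrame:
    """Tidy per-whale/per-image table of metric morphology."""
    rows = []
    for m in morphs:
        row = {"whale_id": m.whale_id, "population": m.population, "BAI": m.bai}
        row.update(m.lengths_m)
        row.update({f"{k}_std": v for k, v in m.standardized.items()})
        rows.append(row)
    return pd.DataFrame(rows)
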