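"""Treatment-plan I/O: DICOM RT Ion Plan reading and the PBSPLAN ASCII file.

A spot-scanning plan is reduced to the information the dose engine needs:
number of fields, beamlets per field, and for each beamlet its nominal
energy, number of protons and (x, y) position at the isocenter.  The
frozen ASCII dialect is PBSPLAN v1:

    PBSPLAN v1
    fields N
    field <label> beamlets M
    E_nom_MeV N_protons x_iso_cm y_iso_cm     (M lines, '#' comments allowed)

MU from DICOM follows the standard ion-plan convention: per-spot meterset
weight x (beam meterset / final cumulative meterset weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mu_model import MUCalibration, protons_for_beamlet

ASCII_HEADER = "PBSPLAN v1"


@dataclass
class BeamletSpec:
    """One spot of a scanned field (positions at the isocenter plane, cm)."""

    energy_nominal: float
    mu: float
    x_iso: float
    y_iso: float
    n_protons: float | None = None

    def __post_init__(self):
        self.energy_nominal = float(self.energy_nominal)
        self.mu = float(self.mu)
        self.x_iso = float(self.x_iso)
        self.y_iso = float(self.y_iso)
        if self.n_protons is not None:
            self.n_protons = float(self.n_protons)
            if self.n_protons < 0:
                raise ValueError("n_protons must be non-negative")
        if self.mu < 0:
            raise ValueError("MU must be non-negative")


@dataclass
class PlanField:
    label: str
    beamlets: list[BeamletSpec] = field(default_factory=list)


@dataclass
class PlanSummary:
    fields: list[PlanField]
    label: str = "plan"

    def __post_init__(self):
        if not self.fields:
            raise ValueError("plan must contain at least one field")

    @property
    def beamlets(self) -> list[BeamletSpec]:
        return [b for f in self.fields for b in f.beamlets]

    @property
    def total_n_protons(self) -> float:
        vals = [b.n_protons for b in self.beamlets]
        if any(v is None for v in vals):
            raise ValueError("plan has beamlets without n_protons")
        return float(sum(vals))


def read_rtplan(path) -> PlanSummary:
    """Read a DICOM RT Ion Plan into a PlanSummary (MU level, no protons).

    One beamlet per (energy layer x scan spot), ordered by field, control
    point (layer) and spot index; positions converted mm -> cm.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    modality = getattr(ds, "Modality", None)
    if modality != "RTION":
        raise ValueError(f"not an RT Ion Plan (Modality={modality!r})")
    if "IonBeamSequence" not in ds:
        raise ValueError("missing attribute IonBeamSequence")

    # beam number -> meterset from the fraction group
    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    fields_out: list[PlanField] = []
    for beam in ds.IonBeamSequence:
        if getattr(beam, "RadiationType", "PROTON") != "PROTON":
            raise ValueError("only proton plans are supported")
        if "IonControlPointSequence" not in beam:
            raise ValueError("missing attribute IonControlPointSequence")
        final_cum = float(beam.FinalCumulativeMetersetWeight)
        beam_mu = metersets.get(int(beam.BeamNumber))
        if beam_mu is None:
            raise ValueError(f"missing BeamMeterset for beam {beam.BeamNumber}")
        scale = beam_mu / final_cum
        beamlets: list[BeamletSpec] = []
        for cp in beam.IonControlPointSequence:
            weights = getattr(cp, "ScanSpotMetersetWeights", None)
            if weights is None:
                raise ValueError("missing attribute ScanSpotMetersetWeights")
            weights = np.atleast_1d(np.asarray(weights, dtype=float))
            if np.all(weights == 0):
                continue  # closing control point of a layer
            energy = float(cp.NominalBeamEnergy)
            pos = np.asarray(cp.ScanSpotPositionMap, dtype=float).reshape(-1, 2)
            if len(pos) != len(weights):
                raise ValueError("ScanSpotPositionMap / weights length mismatch")
            for (x_mm, y_mm), w in zip(pos, weights):
                beamlets.append(BeamletSpec(
                    energy_nominal=energy, mu=float(w) * scale,
                    x_iso=float(x_mm) / 10.0, y_iso=float(y_mm) / 10.0))
        fields_out.append(PlanField(label=str(getattr(beam, "BeamName",
                                                      beam.BeamNumber)),
                                    beamlets=beamlets))
    label = str(getattr(ds, "RTPlanLabel", "plan"))
    return PlanSummary(fields=fields_out, label=label)


def apply_mu_calibration(plan: PlanSummary,
                         calibration: MUCalibration) -> PlanSummary:
    """Attach n_protons = k(E) x MU to every beamlet (new PlanSummary)."""
    lo, hi = calibration.fit_range
    bad = sorted({b.energy_nominal for b in plan.beamlets
                  if not (lo <= b.energy_nominal <= hi)})
    if bad:
        raise ValueError(f"energies outside MU calibration range "
                         f"[{lo}, {hi}] MeV: {bad}")
    new_fields = []
    for f in plan.fields:
        nb = [BeamletSpec(b.energy_nominal, b.mu, b.x_iso, b.y_iso,
                          n_protons=protons_for_beamlet(
                              calibration, b.energy_nominal, b.mu))
              for b in f.beamlets]
        new_fields.append(PlanField(label=f.label, beamlets=nb))
    return PlanSummary(fields=new_fields, label=plan.label)


def write_ascii_plan(plan: PlanSummary, path) -> None:
    """Write the PBSPLAN v1 file.

    Values are printed with the shortest representation that parses back
    to the identical double (always >= the 12 significant digits the
    format guarantees), so read(write(plan)) is bit-exact.
    """
    if any(b.n_protons is None for b in plan.beamlets):
        raise ValueError("plan has beamlets without n_protons; "
                         "apply the MU calibration first")
    with open(path, "w") as fh:
        fh.write(ASCII_HEADER + "\n")
        fh.write(f"fields {len(plan.fields)}\n")
        for f in plan.fields:
            fh.write(f"field {f.label} beamlets {len(f.beamlets)}\n")
            for b in f.beamlets:
                fh.write(f"{b.energy_nominal!r} {float(b.n_protons)!r} "
                         f"{b.x_iso!r} {b.y_iso!r}\n")


def read_ascii_plan(path) -> PlanSummary:
    """Read a PBSPLAN v1 file; errors carry the offending line number."""
    with open(path) as fh:
        raw = fh.readlines()
    lines = []
    for i, ln in enumerate(raw, start=1):
        stripped = ln.split("#", 1)[0].strip()
        if stripped:
            lines.append((i, stripped))
    if not lines or lines[0][1] != ASCII_HEADER:
        raise ValueError(f"line {lines[0][0] if lines else 1}: "
                         f"expected header {ASCII_HEADER!r}")
    if len(lines) < 2 or not lines[1][1].startswith("fields "):
        raise ValueError("line 2: expected 'fields N'")
    n_fields = int(lines[1][1].split()[1])
    fields_out: list[PlanField] = []
    idx = 2
    for _ in range(n_fields):
        if idx >= len(lines) or not lines[idx][1].startswith("field "):
            lineno = lines[idx][0] if idx < len(lines) else lines[-1][0] + 1
            raise ValueError(f"line {lineno}: expected 'field <label> "
                             "beamlets M'")
        parts = lines[idx][1].split()
        label = parts[1]
        n_beamlets = int(parts[3])
        idx += 1
        beamlets = []
        for _ in range(n_beamlets):
            if idx >= len(lines) or len(lines[idx][1].split()) != 4:
                lineno = lines[idx][0] if idx < len(lines) else lines[-1][0] + 1
                raise ValueError(f"line {lineno}: expected 4 beamlet values")
            lineno, txt = lines[idx]
            try:
                e, npr, x, y = (float(v) for v in txt.split())
            except ValueError:
                raise ValueError(f"line {lineno}: malformed beamlet values")
            beamlets.append(BeamletSpec(e, mu=0.0, x_iso=x, y_iso=y,
                                        n_protons=npr))
            idx += 1
        fields_out.append(PlanField(label=label, beamlets=beamlets))
    if idx != len(lines):
        raise ValueError(f"line {lines[idx][0]}: trailing content after "
                         "declared beamlets")
    return PlanSummary(fields=fields_out)


def renormalize_weights(plan: PlanSummary, n_simulated: int) -> np.ndarray:
    """Per-beamlet sampling weights summing to n_simulated, ratios preserved.

    The final doses are to be scaled by total_n_protons / n_simulated.
    """
    if n_simulated <= 0:
        raise ValueError("n_simulated must be positive")
    npr = np.array([b.n_protons for b in plan.beamlets], dtype=float)
    total = npr.sum()
    if total <= 0:
        raise ValueError("plan has zero total protons")
    return npr / total * n_simulated
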