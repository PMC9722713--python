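"""Digitise a scan and export the 13-column spreadsheet.

The CSV's first column is the time axis in ms; the remaining 12 columns
are the leads' voltages in mV.  On a 3x4 page each lead only covers its
own 2.5 s window, so cells outside that window are empty.
"""

from pathlib import Path

from paperecg import digitise_image, save_image, write_csv
from paperecg.synth import generate_synthetic_ecg

out = Path("scratch/example_out")
out.mkdir(parents=True, exist_ok=True)

truth = generate_synthetic_ecg(seed=7, layout_kind="3x4_rhythm")
png = out / "ecg.png"
save_image(truth.image, png)              # what a scanner would hand us

record = digitise_image(png)
csv = out / "ecg.csv"
write_csv(record, csv)

header, first = csv.read_text().splitlines()[:2]
print(f"wrote {csv}")
print(f"columns ({len(header.split(','))}):", header)
print("first sample row:", first)
print("calibration:", record.calibration)
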