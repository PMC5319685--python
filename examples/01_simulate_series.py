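"""Generate a simulated 9-year monthly outpatient-visit series.

The generator overlays a multiplicative seasonal profile (winter peak in
January-February, sharp July dip) on a slowly rising monthly level and
adds Gaussian noise.  Printed below: the first year of counts and the
per-month seasonal fluctuation index (SFI1), which should be largest for
January, February and July.
"""

from emdcast import metrics, synthetic
from emdcast.series import format_month

series = synthetic.generate(synthetic.SimConfig(seed=1))
print(f"{len(series)} months, {format_month(series.start)}..{format_month(series.end)}")
print("\nFirst year of simulated visit counts:")
for label, value in zip(series.labels[:12], series.values[:12]):
    print(f"  {format_month(label)}  {value:8.0f}")

sfi = metrics.sfi1(series)
print("\nSeasonal fluctuation index by calendar month (deviation from the")
print("overall mean level; big values = strongly seasonal months):")
for month, value in zip(
    "Jan Feb Mar Apr May Jun Jul Aug Sep Oct Nov Dec".split(), sfi
):
    print(f"  {month}  {value:.3f}")
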