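"""Full hybrid forecast of the final 13 months of a simulated series.

Pipeline: decompose the series into IMFs + residue, min-max normalize
each component, PSO-search initial weights for a 3-14-1 network per
component, refine by resilient backpropagation on the training span
(through November of year 8), then forecast December of year 8 through
December of year 9 one step ahead and superpose the component forecasts.
"""

from emdcast import forecaster, synthetic
from emdcast.series import format_month

series = synthetic.generate(synthetic.SimConfig(seed=1))
model, report = forecaster.fit_predict(series, (2012, 11), "emd_pso_bpann", seed=0)

print(f"{model.n_components} component networks "
      f"({model.decomposition.n_imfs} IMFs + residue)\n")
print("month     observed  predicted  rel.err")
for label, obs, pred in zip(report.horizon_labels, report.observed, report.predicted):
    print(f"{format_month(label)}   {obs:8.0f}   {pred:8.0f}   {abs(pred-obs)/obs:6.1%}")

m = report.metrics
print(f"\nR={m.R:.4f}  RMSE={m.RMSE:.0f}  MAPE={m.MAPE:.4f}  SSE={m.SSE:.3e}")
print("(R: correlation between forecast and truth; MAPE: mean relative error"
      " as a fraction of the observed count)")
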