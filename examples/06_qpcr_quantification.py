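"""Relative qPCR quantification: normalise the target to the geometric mean
of three reference genes and express each sample as percent of the control
group."""

from asorescue import simulate_ct
from asorescue.qpcr import relative_expression

# three controls at full expression plus one proband at 4.4% residual
# canonical splicing (sigma_Ct = 0.05 cycles, 3 technical replicates)
ct_table, truth = simulate_ct(seed=0)
result = relative_expression(ct_table, "CDK5RAP3")

print(result.round(3).to_string())
print("\ntrue percent of control per sample:")
print(truth.data["true_percent"].round(1).to_string())

# NQ is the target quantity relative to the reference-gene geometric mean;
# percent_of_control rescales so the control-group mean is exactly 100.
# The proband estimate should land close to the planted 4.4%.
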