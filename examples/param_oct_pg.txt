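# Octenidine approaching a bacterial-mimetic (POPG) membrane.
# Any key not given falls back to the documented default.
lipid = PG
agent = OCT
box_x = 80
box_y = 80
half_thickness = 20
apl = 64
z_start = 45
dt = 1e-15
n_steps = 500000
seed = 1
n_replicates = 10
output_dir = out_oct_pg
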