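# Smallest useful model: two cell types, one axonal and one dendritic
# region, one synapse rule.  Micrometres throughout.

model_space 0 100 0 100 0 100
master_seed 7

cell_type source
    density 3e-6                # 3 cells
    layer 0 100 0 100 0 100
    region axon axonal -20 20 -20 20 -20 20

cell_type target
    density 3e-6                # 3 cells
    layer 0 100 0 100 0 100
    region dend dendritic -25 25 -25 25 -25 25

rule source.axon -> target.dend
    density 0.0005
    sign excitatory
    axonal_speed 1000
    dendritic_speed inf 100
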