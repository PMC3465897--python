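# Toy cerebellar cortex patch: three cell types, four cells at default
# densities.  All coordinates in micrometres, densities per cubic
# micrometre, speeds in micrometres per millisecond.
#
# Granule somas pack the lower third of the patch; each sends a long, thin
# parallel-fiber axon box running longitudinally (Y) through the molecular
# layer.  Purkinje dendrites are flat plates thin in Y and much narrower in
# X than the patch; Golgi cells carry a broad axonal field and an ascending
# dendritic box.  Because every parallel fiber spans most of the patch in Y
# while only a sliver of it in X, a sweep along Y is the expensive choice
# and the dynamic walk avoids it.

model_space 0 600 0 600 0 200
master_seed 26

cell_type granule
    density 9.3e-8              # 2 somas in the 600 x 600 x 60 granular layer
    layer 0 600 0 600 0 60
    region axon axonal -3 3 -300 300 100 110     # parallel fiber, long in Y
    region dend dendritic -8 8 -8 8 -8 8         # claw-like dendrites near soma

cell_type purkinje
    density 1.4e-7              # 1 soma in the thin Purkinje layer
    layer 0 600 0 600 60 80
    region dend dendritic -100 100 -4 4 20 140   # flat plate, thin in Y
    region axon axonal -5 5 -5 5 -60 0           # descending axon

cell_type golgi
    density 2.8e-8              # 1 soma
    layer 0 600 0 600 0 100
    region dend dendritic -30 30 -30 30 0 80
    region axon axonal -40 40 -40 40 -40 40

rule granule.axon -> purkinje.dend
    density 0.05                # synapses per um^3 of overlap
    sign excitatory
    axonal_speed 300
    dendritic_speed 100 100
    dendritic_speed inf 50

rule granule.axon -> golgi.dend
    density 0.006
    sign excitatory
    axonal_speed 300
    dendritic_speed 100 100
    dendritic_speed inf 50

rule golgi.axon -> granule.dend
    density 0.01
    sign inhibitory
    axonal_speed 500
    dendritic_speed inf 200
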