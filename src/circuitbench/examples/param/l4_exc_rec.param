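{
"Spikes" : {
    'component': 'circuitbench.sheets.population_selector.RCRandomN',
    'variables': ("spikes",),
    'params':  {'num_of_cells': 1000} },
"DetailedRecordings": {
    'component': 'circuitbench.sheets.population_selector.RCRandomN',
    'variables': ("spikes","v","gsyn_exc","gsyn_inh"),
    'params':  {'num_of_cells': 20} }
}
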