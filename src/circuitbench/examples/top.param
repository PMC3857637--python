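{   'input_space_type': 'VisualSpace',
    'input_space': {
        'update_interval': 7.0, # ms
        'background_luminance': 50.0 }, # cd/m^2
    'retina_lgn': url("param/retina_lgn"),
    'l4_cortex_exc': url("param/l4_cortex_exc"),
    'l4_cortex_inh': url("param/l4_cortex_inh"),
    'visual_field': {
        'centre': (0.0, 0.0), # degrees (x, y)
        'size': (6.8, 6.8) }, # degrees (width, height)
    'results_dir': '',
    'name': 'V1 Model',
    'reset': False,
    'null_stimulus_period': 140.0 }
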