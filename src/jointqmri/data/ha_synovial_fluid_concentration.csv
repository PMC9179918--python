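group,time_days,ha_ng_ml
Healthy,0,243.30
CTR,28,53.21
CTR,56,48.46
CTR,84,71.54
CGH,28,61.35
CGH,56,67.85
CGH,84,59.52
CGH-NC,28,119.62
CGH-NC,56,68.57
CGH-NC,84,90.66
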