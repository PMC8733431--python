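Activate
Affect
Associates
Block
Cause
Contain
Control
Decrease
Detect
Display
Downregulate
Enhance
Express
Find
Inactivate
Increase
Induce
Interacts
Overexpress
Produce
Reduce
Regulate
Release
Reveal
Stimulate
Trigger
Ubiquitination
Upregulates
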