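metric,1G-BF,1G-BE,2G-BF,2G-EF,2G-BE,2G-EE
WT,0.564,0.505,0.575,0.519,0.491,0.525
C-cur,0.630,0.514,0.638,0.516,0.524,0.618
L-cur,1.216,1.186,1.193,1.155,1.263,1.389
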