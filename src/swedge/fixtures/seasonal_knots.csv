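# Monthly knot heights (arbitrary units) for the seasonal MVPA trend shape:
# a smooth single annual cycle with a summer peak and winter trough.  Only
# the shape is used; the trend amplitude is rescaled exactly at build time.
month,height
1,-1.0
2,-0.8660254037844387
3,-0.5
4,0.0
5,0.5
6,0.8660254037844387
7,1.0
8,0.8660254037844387
9,0.5
10,0.0
11,-0.5
12,-0.8660254037844387
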