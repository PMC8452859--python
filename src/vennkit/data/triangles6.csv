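shape_id,ring_id,x,y
0,0,0.637,0.921
0,0,0.649,0.274
0,0,0.188,0.667
0,0,0.637,0.921
1,0,0.981,0.769
1,0,0.335,0.191
1,0,0.393,0.671
1,0,0.981,0.769
2,0,0.941,0.397
2,0,0.292,0.475
2,0,0.456,0.747
2,0,0.941,0.397
3,0,0.662,0.119
3,0,0.316,0.548
3,0,0.662,0.7
3,0,0.662,0.119
4,0,0.309,0.081
4,0,0.374,0.718
4,0,0.681,0.488
4,0,0.309,0.081
5,0,0.016,0.626
5,0,0.726,0.687
5,0,0.522,0.327
5,0,0.016,0.626
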