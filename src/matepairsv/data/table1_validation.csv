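sample,type,attempted,non_validated,constitutional,somatic
113 T,deletion,8,8,0,0
113 T,inversion,0,0,0,0
113 T,translocation,2,2,0,0
114 T,deletion,5,4,1,0
114 T,inversion,0,0,0,0
114 T,translocation,5,2,3,0
116 T,deletion,1,0,1,0
116 T,inversion,4,2,0,2
116 T,translocation,1,0,0,1
117 T,deletion,0,0,0,0
117 T,inversion,0,0,0,0
117 T,translocation,1,0,1,0
118 T,deletion,3,1,2,0
118 T,inversion,0,0,0,0
118 T,translocation,12,5,1,6
119 T,deletion,1,0,0,1
119 T,inversion,3,3,0,0
119 T,translocation,3,0,0,3
120 T,deletion,3,0,3,0
120 T,inversion,3,2,0,1
120 T,translocation,3,0,0,3
147 T,deletion,2,0,2,0
147 T,inversion,0,0,0,0
147 T,translocation,0,0,0,0
148 T,deletion,4,0,4,0
148 T,inversion,5,5,0,0
148 T,translocation,8,3,3,2
149 T,deletion,16,4,8,4
149 T,inversion,1,0,0,1
149 T,translocation,9,4,1,4
150 T,deletion,5,1,4,0
150 T,inversion,1,1,0,0
150 T,translocation,0,0,0,0
151 T,deletion,4,0,4,0
151 T,inversion,1,0,0,1
151 T,translocation,1,1,0,0
152 T,deletion,1,0,0,1
152 T,inversion,0,0,0,0
152 T,translocation,0,0,0,0
153 T,deletion,19,9,9,1
153 T,inversion,6,3,3,0
153 T,translocation,12,3,3,6
154 T,deletion,7,1,5,1
154 T,inversion,1,0,0,1
154 T,translocation,4,1,2,1
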