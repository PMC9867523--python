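class,mean_x,sd_x,max_x,min_x,mean_y,sd_y,max_y,min_y
P1,15.25,0.37,15.94,14.52,3.20,0.66,4.59,1.36
P2,15.20,0.36,16.08,14.27,5.99,0.68,8.66,4.67
P3,15.07,0.44,16.22,14.08,9.23,0.96,11.32,7.57
P4,15.45,0.49,16.77,14.26,2.26,2.10,6.39,0.00
P5,19.60,0.88,21.69,17.62,3.63,0.78,5.03,1.72
P6,10.83,0.99,12.80,7.96,3.92,0.79,6.05,2.05
P7,16.79,0.84,18.46,15.08,3.43,1.33,6.76,0.82
P8,13.63,0.79,14.78,11.51,3.32,1.46,6.46,0.38
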