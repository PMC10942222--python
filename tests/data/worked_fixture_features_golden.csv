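video_id,count.grasp.L,count.grasp.R,count.inefficient_grasp.L,count.inefficient_grasp.R,count.push.L,count.push.R,count.pull.L,count.pull.R,count.spread.L,count.spread.R,count.retract.L,count.retract.R,count.hook,count.inefficient_hook,count.blunt_dissection,count.cut,count.clip,count.coagulate,count.suction,count.irrigate,dur.grasp.L,dur.grasp.R,dur.inefficient_grasp.L,dur.inefficient_grasp.R,dur.push.L,dur.push.R,dur.pull.L,dur.pull.R,dur.spread.L,dur.spread.R,dur.retract.L,dur.retract.R,dur.hook,dur.inefficient_hook,dur.blunt_dissection,dur.cut,dur.clip,dur.coagulate,dur.suction,dur.irrigate,int.all.mean,int.all.max,int.all.min,int.all.sd,int.left.mean,int.left.max,int.left.min,int.left.sd,int.right.mean,int.right.max,int.right.min,int.right.sd,shift.all,shift.left,shift.right,de.count_D,de.count_E,de.dur_D,de.dur_E,de.count_ratio,de.dur_ratio,de.shift,manip_time
V001,3.0,0.0,0.0,0.0,0.0,2.0,0.0,0.0,0.0,0.0,0.0,0.0,3.0,1.0,1.0,1.0,1.0,1.0,1.0,0.0,41.0,0.0,0.0,0.0,0.0,13.5,0.0,0.0,0.0,0.0,0.0,0.0,27.0,5.0,8.0,3.0,6.0,6.0,5.0,0.0,1.3333333333333333,6.0,0.0,1.8748737331221847,18.0,18.0,18.0,0.0,0.0,0.0,0.0,0.0,7.826086956521738,0.0,0.0,8.0,6.0,55.0,59.5,1.3333333333333333,0.9243697478991597,4.565217391304348,1.5333333333333334
V002,1.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,15.0,0.0,15.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,20.0,0.0,10.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.0,1.0,0.0,3.0,2.0,30.0,30.0,1.5,1.0,0.0,1.0
V003,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.0,0.0,0.0,1.0,0.0,1.0,0.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,15.0,0.0,0.0,20.0,0.0,30.0,0.0,0.0,15.0,0.0,0.0,5.0,5.0,5.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.2,0.0,0.0,4.0,0.0,80.0,0.0,4.0,80.0,0.0,1.6666666666666667
V004,1.0,0.0,0.0,0.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,20.0,0.0,0.0,0.0,0.0,20.0,0.0,0.0,0.0,0.0,0.0,0.0,15.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,5.0,10.0,0.0,7.0710678118654755,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.5,0.0,0.0,1.0,2.0,15.0,40.0,0.5,0.375,0.75,1.3333333333333333
V005,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.0
V006,0.0,0.0,0.0,2.0,0.0,1.0,0.0,1.0,0.0,0.0,0.0,0.0,0.0,2.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,16.0,0.0,13.0,0.0,13.0,0.0,0.0,0.0,0.0,0.0,26.0,0.0,0.0,0.0,0.0,0.0,0.0,2.5,4.0,2.0,1.0,0.0,0.0,0.0,0.0,8.0,12.0,4.0,5.656854249492381,2.0,0.0,0.6666666666666666,2.0,4.0,26.0,42.0,0.5,0.6190476190476191,2.0,1.5
V007,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,30.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,15.0,20.0,10.0,7.0710678118654755,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3.0,0.0,30.0,0.0,3.0,30.0,0.0,2.0
V008,3.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,24.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,26.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.0,2.0,2.0,0.0,12.0,12.0,12.0,0.0,0.0,0.0,0.0,0.0,2.5,0.0,0.0,3.0,3.0,26.0,24.0,1.0,1.0833333333333333,2.5,2.0
V009,0.0,0.0,0.0,0.0,1.0,1.0,1.0,0.0,0.0,1.0,1.0,0.0,0.0,0.0,1.0,1.0,1.0,1.0,1.0,1.0,0.0,0.0,0.0,0.0,7.0,8.0,7.0,0.0,0.0,5.0,10.0,0.0,0.0,0.0,12.0,2.0,4.0,8.0,5.0,6.0,1.3333333333333333,5.0,0.0,1.5000000000000002,16.0,16.0,16.0,0.0,0.0,0.0,0.0,0.0,6.0,0.75,0.0,5.0,6.0,31.0,43.0,0.8333333333333334,0.7209302325581395,3.0,1.3333333333333333
V010,0.0,2.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,50.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,45.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.4,0.0,0.0,2.0,2.0,45.0,50.0,1.0,0.9,2.4,0.8333333333333334
V011,2.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3.0,0.0,1.0,1.0,1.0,0.0,0.0,0.0,48.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,24.0,0.0,18.0,2.0,4.0,0.0,0.0,0.0,0.8333333333333334,2.0,0.0,0.752772652709081,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,3.8709677419354835,0.0,0.0,6.0,2.0,48.0,48.0,3.0,1.0,1.9354838709677418,1.0333333333333334
V012,0.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,2.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,14.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,29.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.0,1.0,1.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,1.7142857142857142,0.0,0.0,2.0,1.0,29.0,14.0,2.0,2.0714285714285716,1.7142857142857142,1.1666666666666667
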