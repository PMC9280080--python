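subject,test,rms_mean,rms_max,rms_min,fmean_mean,fmean_max,fmean_min,fmed_mean,fmed_max,fmed_min,bandmag_mean,bandmag_max,bandmag_min
1,1,162.4,292.2,112.5,65.4,69.3,59.8,56.1,62.6,47.8,13.6,23.5,10.2
1,2,156.6,249.6,119.4,68.4,77.6,65.5,58.0,64.9,52.1,12.7,16.7,9.4
2,1,570.8,818.1,274.7,67.5,73.5,63.4,56.2,62.3,50.5,50.1,69.2,26.3
2,2,588.8,894.1,476.2,70.6,80.3,63.0,57.8,67.3,51.4,69.1,97.4,36.1
3,1,289.3,354.8,212.9,81.5,83.9,77.1,70.7,73.5,66.5,36.5,48.9,21.2
3,2,293.9,393.4,218.4,81.2,87.7,77.1,70.5,75.3,66.7,36.1,43.4,24.4
4,1,423.2,592.7,342.7,68.1,74.4,62.0,60.1,66.2,49.3,40.2,51.3,24.2
4,2,487.1,606.4,359.9,66.5,71.3,61.9,58.1,66.0,48.5,41.6,51.3,29.0
5,1,391.5,564.8,198.9,71.3,78.8,64.8,61.8,71.3,53.6,44.3,63.4,24.3
5,2,642.5,930.4,302.6,70.1,78.4,60.4,59.4,59.4,48.1,54.1,70.9,24.9
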